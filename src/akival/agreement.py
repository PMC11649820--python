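"""Chance-corrected inter-rater agreement for ordinal stage pairs.

Implements the weighted first-order agreement coefficient (AC1) of Gwet,
which corrects observed agreement for chance using marginal category
prevalences and is robust when one category dominates (here: the huge
stage-0 cell).  Partial credit for near-miss disagreements comes from an
ordinal weight matrix.

For two raters and ``q`` categories with cell proportions ``p_kl``,
weights ``w_kl`` and mean marginals ``pi_k = (row_k + col_k) / 2``::

    pa = sum_kl w_kl p_kl
    pe = [sum_kl w_kl / (q (q - 1))] * sum_k pi_k (1 - pi_k)
    coefficient = (pa - pe) / (1 - pe)

The standard error uses Gwet's closed-form two-rater linearisation
(subjects as independent units); a seeded multinomial bootstrap is provided
as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up

#: Landis-Koch interpretation bands, upper-inclusive
_BANDS = [(0.0, "poor"), (0.20, "slight"), (0.40, "fair"),
          (0.60, "moderate"), (0.80, "substantial"), (1.0, "almost perfect")]
ACCEPTABLE_THRESHOLD = 0.61


@dataclass(frozen=True)
class ConfusionMatrix:
    """q x q cross-tabulation: rows = local stage, columns = central stage."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def q(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def percents(self, ndigits: int = 2) -> np.ndarray:
        """Cell percentages of the grand total, half-up rounded."""
        pct = self.counts / self.n * 100.0
        return np.vectorize(lambda x: round_half_up(x, ndigits))(pct)

    def drop_local_stage(self, stage: int) -> "ConfusionMatrix":
        """Zero one local-stage row, keeping all q categories (complete case)."""
        out = self.counts.copy()
        out[stage, :] = 0
        return ConfusionMatrix(out)

    @classmethod
    def from_pairs(cls, local: np.ndarray, central: np.ndarray,
                   q: int = 4) -> "ConfusionMatrix":
        counts = np.zeros((q, q))
        np.add.at(counts, (np.asarray(local, int), np.asarray(central, int)), 1)
        return cls(counts)


@dataclass(frozen=True)
class AgreementResult:
    coefficient: float
    pa_weighted: float
    pa_unweighted: float
    pe: float
    se: float
    ci95: tuple[float, float]
    band: str
    acceptable: bool
    n: float
    q: int

    def to_dict(self) -> dict:
        return {"coefficient": self.coefficient, "pa_weighted": self.pa_weighted,
                "pa_unweighted": self.pa_unweighted, "pe": self.pe,
                "se": self.se, "ci95": list(self.ci95), "band": self.band,
                "acceptable": self.acceptable, "n": self.n}


def ordinal_weights(q: int, family: str = "ordinal") -> np.ndarray:
    """Agreement weight matrix for ``q`` ordered categories.

    ``family``:
      * ``ordinal`` (default): ``w = 1 - C(d+1, 2) / C(q, 2)`` for stage
        distance ``d`` - for q=4 the off-diagonals are 5/6, 1/2, 0;
      * ``linear``: ``1 - d/(q-1)``;
      * ``quadratic``: ``1 - (d/(q-1))^2``;
      * ``identity``: exact agreement only.
    """
    if q < 2:
        raise ValueError("need at least 2 categories")
    d = np.abs(np.subtract.outer(np.arange(q), np.arange(q)))
    if family == "ordinal":
        penal = np.vectorize(lambda x: comb(int(x) + 1, 2))(d)
        return 1.0 - penal / comb(q, 2)
    if family == "linear":
        return 1.0 - d / (q - 1)
    if family == "quadratic":
        return 1.0 - (d / (q - 1)) ** 2
    if family == "identity":
        return (d == 0).astype(float)
    raise ValueError(f"unknown weight family {family!r}")


def landis_koch_band(coefficient: float) -> str:
    """Interpretation label for an agreement coefficient in [-1, 1]."""
    if not -1.0 <= coefficient <= 1.0:
        raise ValueError(f"coefficient {coefficient} outside [-1, 1]")
    if coefficient < 0:
        return "poor"
    for upper, label in _BANDS[1:]:
        if coefficient <= upper:
            return label
    return "almost perfect"


def gwet_coefficient(m: ConfusionMatrix, w: np.ndarray | None = None,
                     ) -> AgreementResult:
    """Weighted AC1 with closed-form standard error and 95% CI.

    ``w`` defaults to the ordinal family for ``m.q`` categories; pass
    ``ordinal_weights(q, "identity")`` for the unweighted coefficient.
    """
    q = m.q
    if w is None:
        w = ordinal_weights(q)
    w = np.asarray(w, float)
    if w.shape != (q, q):
        raise ValueError("weight matrix shape mismatch")
    n = m.n
    if n <= 0:
        raise ValueError("empty confusion matrix")

    p = m.counts / n
    pa = float((w * p).sum())
    pa_unweighted = float(np.trace(p))
    pi = (p.sum(axis=1) + p.sum(axis=0)) / 2.0
    tw = w.sum()
    pe = float(tw / (q * (q - 1)) * (pi * (1 - pi)).sum())
    if pe >= 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1")
    gamma = (pa - pe) / (1 - pe)

    # Gwet's two-rater linearised variance, computed over the 16 cell types.
    k_idx, l_idx = np.meshgrid(np.arange(q), np.arange(q), indexing="ij")
    # per-subject marginal indicator pi_{j|s} = (1[k=j] + 1[l=j]) / 2
    pe_s = np.zeros((q, q))
    for j in range(q):
        pij_s = ((k_idx == j).astype(float) + (l_idx == j)) / 2.0
        pe_s += pij_s * (1 - pi[j])
    pe_s *= tw / (q * (q - 1))
    gamma_s = (w - pe) / (1 - pe)
    gamma_star = gamma_s - 2 * (1 - gamma) * (pe_s - pe) / (1 - pe)
    if n > 1:
        var = float((p * (gamma_star - gamma) ** 2).sum() / (n - 1))
        se = var ** 0.5
        tcrit = float(stats.t.ppf(0.975, n - 1))
        ci = (gamma - tcrit * se, gamma + tcrit * se)
    else:
        se, ci = float("nan"), (float("nan"), float("nan"))

    band = landis_koch_band(min(max(gamma, -1.0), 1.0))
    return AgreementResult(coefficient=gamma, pa_weighted=pa,
                           pa_unweighted=pa_unweighted, pe=pe, se=se,
                           ci95=ci, band=band,
                           acceptable=gamma >= ACCEPTABLE_THRESHOLD,
                           n=n, q=q)


def bootstrap_se(m: ConfusionMatrix, w: np.ndarray | None = None,
                 n_boot: int = 1000, seed: int = 0) -> float:
    """Multinomial-bootstrap standard error of the weighted coefficient."""
    rng = np.random.default_rng(seed)
    n = int(m.n)
    probs = (m.counts / m.n).ravel()
    q = m.q
    coefs = np.empty(n_boot)
    for b in range(n_boot):
        counts = rng.multinomial(n, probs).reshape(q, q)
        coefs[b] = gwet_coefficient(ConfusionMatrix(counts), w).coefficient
    return float(coefs.std(ddof=1))


def percent_positive_agreement(m: ConfusionMatrix,
                               w: np.ndarray | None = None,
                               ) -> dict[str, float]:
    """Diagonal share of paired results, unweighted and weighted.

    The unweighted value is the sum of diagonal proportions; the weighted
    value is the weighted observed agreement ``pa``.  Both are returned
    because report tables do not always say which they print.
    """
    if m.n <= 0:
        raise ValueError("empty confusion matrix")
    if w is None:
        w = ordinal_weights(m.q)
    p = m.counts / m.n
    return {"unweighted": float(np.trace(p)),
            "weighted": float((np.asarray(w) * p).sum())}


def cross_tabulate(local: "pd.Series | np.ndarray",
                   central: "pd.Series | np.ndarray",
                   q: int = 4) -> ConfusionMatrix:
    """Cross-tabulate paired local vs central stages into a q x q matrix."""
    local = np.asarray(local)
    central = np.asarray(central)
    if len(local) != len(central):
        raise ValueError("stage vectors differ in length")
    if ((local < 0) | (local >= q) | (central < 0) | (central >= q)).any():
        raise ValueError(f"stages must lie in 0..{q - 1}")
    return ConfusionMatrix.from_pairs(local, central, q=q)


def matrix_report(m: ConfusionMatrix) -> pd.DataFrame:
    """Frequencies, cell percents and marginals in report layout."""
    labels = [str(k) for k in range(m.q)]
    freq = pd.DataFrame(m.counts.astype(int), index=labels, columns=labels)
    freq["Total"] = m.row_totals.astype(int)
    freq.loc["Total"] = list(m.col_totals.astype(int)) + [int(m.n)]
    pct = freq / m.n * 100.0
    out = pd.concat({"frequency": freq, "percent": pct.round(2)}, axis=1)
    out.index.name = "local_stage"
    return out
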