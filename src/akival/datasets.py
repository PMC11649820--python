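"""Published summary data from the national registry audit of AKI e-alerts.

These are the printed aggregate tables of the audit this package models:
the pooled 4x4 cross-tabulation of locally issued versus centrally
recomputed stages, and the per-stage alert counts.  They are the only
study-level inputs that can be redistributed; record-level registry data
are not public.
"""

from __future__ import annotations

import numpy as np

from .agreement import ConfusionMatrix

#: Pooled cross-tabulation of paired stages; rows = local stage 0..3,
#: columns = central stage 0..3.  Grand total 9,096,667 creatinine results.
AUDIT_CROSS_TAB = np.array([
    [7_260_258, 165_802, 46_541, 44_433],
    [167_922, 788_731, 21_288, 10_343],
    [30_252, 23_711, 229_065, 7_970],
    [30_522, 63_430, 45_053, 161_346],
], dtype=np.int64)

#: Non-zero alert counts by stage as received from laboratories.
LOCAL_STAGE_COUNTS = {1: 988_284, 2: 290_998, 3: 300_351}
#: Printed headline total of local non-zero alerts.  It differs from the
#: cross-tab row sum (1,579,633) by 30: the source tables are internally
#: inconsistent at that level.
LOCAL_TOTAL_PRINTED = 1_579_663

#: Non-zero alert counts by stage as recomputed centrally.
CENTRAL_STAGE_COUNTS = {1: 1_067_239, 2: 349_405, 3: 230_206}
CENTRAL_TOTAL_PRINTED = 1_646_850


def audit_confusion_matrix() -> ConfusionMatrix:
    """The pooled audit cross-tabulation as a :class:`ConfusionMatrix`."""
    return ConfusionMatrix(AUDIT_CROSS_TAB.copy())
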