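mpi,lab_code,alert_dt,stage,scr_at_alert
P000000,LAB00,2018-06-07T16:29,1,118.9
P000000,LAB00,2018-06-08T00:46,2,143.4
P000000,LAB00,2018-06-08T13:38,2,147.7
P000000,LAB00,2018-06-09T02:11,2,143.5
P000000,LAB00,2018-06-09T06:28,1,132
P000000,LAB00,2018-06-09T09:18,2,138
P000000,LAB00,2018-06-10T15:53,1,118.7
P000000,LAB00,2018-06-11T16:29,1,117.4
P000000,LAB00,2018-06-12T03:53,1,114.1
P000000,LAB00,2018-06-13T04:01,1,108.6
P000001,LAB01,2018-07-02T12:45,1,191.7
P000001,LAB01,2018-07-03T08:18,1,193.8
P000001,LAB01,2018-07-05T13:00,1,179.1
P000002,LAB01,2018-03-27T00:24,1,158.6
P000002,LAB01,2018-03-28T05:43,2,249.3
P000002,LAB01,2018-11-29T04:26,1,183.7
P000003,LAB00,2018-03-10T16:02,3,286.5
P000003,LAB00,2018-03-14T13:08,1,153.3
P000003,LAB00,2018-03-14T17:45,1,128.6
P000003,LAB00,2018-03-15T15:36,1,140.3
P000004,LAB01,2018-03-02T07:53,2,137.7
P000004,LAB01,2018-03-02T23:17,2,174.9
P000004,LAB01,2018-03-03T03:38,2,175.4
P000004,LAB01,2018-03-04T07:27,3,276.9
P000004,LAB01,2018-03-04T10:37,3,266.9
P000004,LAB01,2018-03-08T10:13,2,183.4
P000004,LAB01,2018-03-08T16:32,2,181
P000004,LAB01,2018-03-09T11:05,2,155.4
P000005,LAB00,2018-09-13T07:25,1,101.1
P000005,LAB00,2018-09-13T12:52,1,101.6
P000006,LAB00,2018-03-28T06:19,1,68.3
P000006,LAB00,2018-03-28T12:53,1,73.5
P000006,LAB00,2018-10-06T00:32,1,73.1
P000006,LAB00,2018-10-06T16:07,1,74.2
P000006,LAB00,2018-10-07T08:41,1,73.8
P000007,LAB00,2018-09-10T23:41,2,266.5
P000007,LAB00,2018-09-11T02:21,2,254.3
P000007,LAB00,2018-09-11T08:36,2,239
P000007,LAB00,2018-09-12T08:14,1,211.7
P000007,LAB00,2018-09-13T01:57,1,188.6
P000007,LAB00,2018-09-13T18:35,1,184.3
P000007,LAB00,2018-09-13T18:45,1,189.8
P000008,LAB00,2018-04-13T09:18,1,47.9
P000008,LAB00,2018-04-13T22:28,1,45
P000008,LAB00,2018-04-16T03:30,1,47.2
P000009,LAB00,2018-03-24T02:59,1,96.5
P000009,LAB00,2018-03-24T19:32,1,105
P000009,LAB00,2018-03-25T16:24,2,124.1
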