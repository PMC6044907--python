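# Minimal design separating day, session and residual variance:
# two back-to-back scans in one session on day 1, then one scan in each
# of two sessions on day 2.
occasions: [scan1, scan2, scan3, scan4]
facets:
  day:
    scan1: d1
    scan2: d1
    scan3: d2
    scan4: d2
  session:
    scan1: s1
    scan2: s1
    scan3: s2
    scan4: s3
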