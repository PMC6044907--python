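# Three scans in a single day: scans 1 and 2 back-to-back in one
# session, scan 3 after repositioning in a second session.  Separates
# session-specific (repositioning) variance from true-score and
# residual variance; day variance is not identifiable here.
occasions: [scan1, scan2, scan3]
facets:
  session:
    scan1: s1
    scan2: s1
    scan3: s2
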