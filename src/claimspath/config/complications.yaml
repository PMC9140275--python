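# ICD-10 prefix sets defining potential treatment complications.  A patient is
# flagged for a condition only when its first matching code appears strictly
# after the cohort index date and no matching code exists during or before any
# prior line of therapy.  The exact membership of these sets is a configuration
# choice (the source literature cites but does not print them); edit per study.

heart:
  [I20, I21, I22, I23, I24, I25, I42, I50]
kidney:
  [N17, N18, N19]
liver:
  [K70, K71, K72, K73, K74, K75, K76, K77]
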