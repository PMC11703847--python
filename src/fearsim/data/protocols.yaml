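# Behavioural protocol suite.  Each group is an ordered list of phases;
# `count` episodes of `expr` are run back-to-back, then the behavioural
# clock advances by `gap_min` minutes (day boundaries are 1440 min; the
# immediate-extinction protocol uses an explicit 15-minute gap).
cfc:
  title: Contextual fear conditioning (acquisition, extinction, renewal)
  groups:
    "1":
      - {label: CFC1, count: 5, expr: AX+, gap_min: 1440}
      - {label: CFC2, count: 15, expr: BX-, gap_min: 1440}
      - {label: CFC3, count: 3, expr: AX-}
    "2":
      - {label: CFC1, count: 5, expr: AX+, gap_min: 1440}
      - {label: CFC2, count: 15, expr: BX-, gap_min: 1440}
      - {label: CFC3, count: 3, expr: BX-}

shock_magnitude:
  title: Fear response at different shock magnitudes
  groups:
    "1":
      - {label: SM1, count: 2, expr: AX+, gap_min: 1440}
      - {label: SM2, count: 15, expr: BX-}
    "2":
      - {label: SM1, count: 10, expr: AX+, gap_min: 1440}
      - {label: SM2, count: 15, expr: BX-}
    "3":
      - {label: SM1, count: 20, expr: AX+, gap_min: 1440}
      - {label: SM2, count: 15, expr: BX-}
    "4":
      - {label: SM1, count: 30, expr: AX+, gap_min: 1440}
      - {label: SM2, count: 15, expr: BX-}

sefl:
  title: Stress-enhanced fear learning
  groups:
    "1":
      - {label: SEFL1, count: 15, expr: A, gap_min: 1440}
      - {label: SEFL2, count: 1, expr: B, gap_min: 1440}
      - {label: SEFL3, count: 1, expr: B}
    "2":
      - {label: SEFL1, count: 15, expr: A, gap_min: 1440}
      - {label: SEFL2, count: 1, expr: B+, gap_min: 1440}
      - {label: SEFL3, count: 1, expr: B}
    "3":
      - {label: SEFL1, count: 15, expr: A+, gap_min: 1440}
      - {label: SEFL2, count: 1, expr: B, gap_min: 1440}
      - {label: SEFL3, count: 1, expr: B}
    "4":
      - {label: SEFL1, count: 15, expr: A+, gap_min: 1440}
      - {label: SEFL2, count: 1, expr: B+, gap_min: 1440}
      - {label: SEFL3, count: 1, expr: B}

shock_stress:
  title: Shock stress must precede fear conditioning
  groups:
    "1":
      - {label: SS1, count: 1, expr: B, gap_min: 1440}
      - {label: SS2, count: 15, expr: A, gap_min: 1440}
      - {label: SS3, count: 1, expr: B, gap_min: 1440}
      - {label: SS4, count: 1, expr: A}
    "2":
      - {label: SS1, count: 1, expr: B, gap_min: 1440}
      - {label: SS2, count: 15, expr: A+, gap_min: 1440}
      - {label: SS3, count: 1, expr: B, gap_min: 1440}
      - {label: SS4, count: 1, expr: A}
    "3":
      - {label: SS1, count: 1, expr: B+, gap_min: 1440}
      - {label: SS2, count: 15, expr: A, gap_min: 1440}
      - {label: SS3, count: 1, expr: B, gap_min: 1440}
      - {label: SS4, count: 1, expr: A}
    "4":
      - {label: SS1, count: 1, expr: B+, gap_min: 1440}
      - {label: SS2, count: 15, expr: A+, gap_min: 1440}
      - {label: SS3, count: 1, expr: B, gap_min: 1440}
      - {label: SS4, count: 1, expr: A}

ied:
  title: Immediate extinction deficit
  groups:
    "1":
      - {label: IED1, count: 5, expr: AX+, gap_min: 15}
      - {label: IED2, count: 5, expr: BX-, gap_min: 1440}
      - {label: Home, count: 1, expr: Home, gap_min: 1440}
      - {label: IED3, count: 3, expr: CX-}
    "2":
      - {label: IED1, count: 5, expr: AX+, gap_min: 0}
      - {label: Home, count: 1, expr: Home, gap_min: 1440}
      - {label: IED2, count: 5, expr: BX-, gap_min: 1440}
      - {label: IED3, count: 3, expr: CX-}
    "3":
      - {label: IED1, count: 5, expr: AX+, gap_min: 15}
      - {label: IED2, count: 5, expr: B, gap_min: 1440}
      - {label: Home, count: 1, expr: Home, gap_min: 1440}
      - {label: IED3, count: 3, expr: CX-}
    "4":
      - {label: IED1, count: 5, expr: AX+, gap_min: 0}
      - {label: Home, count: 1, expr: Home, gap_min: 1440}
      - {label: IED2, count: 5, expr: B, gap_min: 1440}
      - {label: IED3, count: 3, expr: CX-}
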