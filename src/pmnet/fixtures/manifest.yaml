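# Printed summary tables from the Sacramento winter 2016/17 19-sensor AirBeam
# campaign, transcribed exactly as published. These are the only field-data
# artifacts shipped with the package; all other inputs are simulated.
tables:
  table1:
    file: table1.csv
    description: >
      Collocation precision and correction-factor table: per-sensor N, R2,
      RMSE, regression slope/intercept versus the 19-sensor hourly mean for
      the pre- and post-study collocation periods, plus the averaged
      correction-factor columns (published table 1).
    units: RMSE and intercepts in ug/m3; slopes and R2 unitless
  table3:
    file: table3.csv
    description: >
      Pairwise great-circle distances between the 15 deployment sites,
      lower triangle as printed (published table 3).
    units: km
  table4:
    file: table4.csv
    description: >
      Pairwise Pearson R2 between the 15 deployment sites; hourly values in
      the lower-left triangle, daily-average values in the upper-right
      triangle, unit diagonal (published table 4).
    units: unitless
  table5:
    file: table5.csv
    description: >
      Pairwise coefficient of divergence (COD) between the 15 deployment
      sites; hourly values in the lower-left triangle, daily-average values
      in the upper-right triangle, zero diagonal (published table 5).
    units: unitless
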