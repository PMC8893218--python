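# 22-item methodological-quality checklist for total sleep deprivation
# memory experiments, grouped into four clusters: reporting, internal
# validity - bias, internal validity - confounding, and power.
#
# The item-to-cluster assignment below is a provisional default
# (reporting 6 items, bias 7, confounding 6, power 3, consistent with the
# cluster score granularities seen in published summaries of such
# checklists); it is data, not code — edit this file or pass a custom
# cluster map to use a different instrument.
items:
  - {id: q01, cluster: reporting, text: "Exclusion of participants with a history of sleep disorders reported"}
  - {id: q02, cluster: reporting, text: "Exclusion of participants with psychiatric/neurological conditions reported"}
  - {id: q03, cluster: reporting, text: "Exclusion of shift workers / recent transmeridian travel reported"}
  - {id: q04, cluster: reporting, text: "Habitual sleep schedule inclusion criteria reported"}
  - {id: q05, cluster: reporting, text: "Caffeine/alcohol/drug restrictions before and during the protocol reported"}
  - {id: q06, cluster: reporting, text: "Demographics (age, sex) of the analysed sample reported"}
  - {id: q07, cluster: bias, text: "Sleep deprivation verified by human observation during the night"}
  - {id: q08, cluster: bias, text: "Daytime wakefulness before testing monitored to the same standard"}
  - {id: q09, cluster: bias, text: "Interference for the deprivation group low (nondemanding activities, monitored in lab)"}
  - {id: q10, cluster: bias, text: "Control group slept at home/lab with sleep verified (actigraphy, polysomnography or diary)"}
  - {id: q11, cluster: bias, text: "Memory task administered at matched circadian time across groups"}
  - {id: q12, cluster: bias, text: "Outcome scoring blind to condition or objectively scored"}
  - {id: q13, cluster: bias, text: "Pre-experimental sleep monitored (actigraphy or sleep diary)"}
  - {id: q14, cluster: confounding, text: "Random allocation to groups (between designs)"}
  - {id: q15, cluster: confounding, text: "Condition order counterbalanced (within designs)"}
  - {id: q16, cluster: confounding, text: "Groups matched or compared on baseline memory/learning performance"}
  - {id: q17, cluster: confounding, text: "Groups matched on age and sex"}
  - {id: q18, cluster: confounding, text: "Sleepiness/fatigue at test measured and reported"}
  - {id: q19, cluster: confounding, text: "Washout between conditions of at least one week (within designs)"}
  - {id: q20, cluster: power, text: "A priori power analysis reported with power >= 80% and alpha <= .05"}
  - {id: q21, cluster: power, text: "Sample size justified relative to the targeted effect size"}
  - {id: q22, cluster: power, text: "Achieved sample met the planned sample size"}
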