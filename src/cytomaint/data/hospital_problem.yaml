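# Reference group-decision instance for maintenance-policy selection in
# hospital cytostatic-drug preparation systems.  Judgements are the hospital
# decision group's consensus (a single decision maker); intervals carry the
# modal value the group recorded, so they resolve as given.
schema: cytomaint/problem-v1
criteria:
  - name: QH
    direction: benefit
    descriptor: >-
      Quality of health care: impact on care as a function of the mean
      availability of the alternative, from no stoppages (availability above
      0.9990) down to critical service reduction (below 0.9960).
  - name: MC
    direction: cost
    descriptor: >-
      Maintenance costs: annual maintenance of all sections of the system,
      levels from EUR 2000 (best) to EUR 8000 (worst).
  - name: IC
    direction: cost
    descriptor: >-
      Investment costs: mean investment per hood including installation,
      amortised over 10 years; levels from EUR 0 (best) to EUR 6000 (worst).
  - name: MP
    direction: benefit
    descriptor: >-
      Maintenance planning optimisation: certainty of fault diagnosis and how
      far in advance corrective work can be programmed.
  - name: IH
    direction: benefit
    descriptor: >-
      Impact on health care: effect on regional health cover and the ability
      to attend to areas beyond the hospital's own catchment.
  - name: WO
    direction: benefit
    descriptor: >-
      Working environment in the organisation: equality among care services
      and the effect on the hospital's regional standing.
alternatives: [CPM, CPM+C, CPM+2C, CPPM]
decision_makers: [group]
weights:
  group:
    QH: ML
    MC: {interval: [L, ML], modal: 0.3}
    IC: {interval: [L, ML], modal: 0.3}
    MP: L
    IH: L
    WO: VL
ratings:
  group:
    CPM:
      QH: VP
      MC: VG
      IC: VG
      MP: F
      IH: MP
      WO: F
    CPM+C:
      QH: VG
      MC: MG
      IC: {interval: [F, MG], modal: 6}
      MP: {interval: [MG, G], modal: 7.5}
      IH: F
      WO: {interval: [MG, G], modal: 7.5}
    CPM+2C:
      QH: VG
      MC: {interval: [F, MG], modal: 6}
      IC: P
      MP: {interval: [MG, G], modal: 7.5}
      IH: {interval: [G, VG], modal: 8.5}
      WO: {interval: [MG, G], modal: 7.5}
    CPPM:
      QH: G
      MC: VP
      IC: VG
      MP: VG
      IH: MP
      WO: {interval: [MG, G], modal: 7.5}
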