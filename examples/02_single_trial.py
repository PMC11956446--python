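"""Walk one simulated sequential trial through both looks.

A scenario with a real benefit (treatment event rate 0.2 vs control 0.4)
and acceptable discontinuation (0.1 < m = 0.2) is simulated once; the
interim decision and, if the trial continues, the final decision are
printed together with the posterior evidence behind them.
"""

from splinetrial import DesignConfig, Scenario, run_trial, \
    uninformative_priors

sc = Scenario(pi_t=0.2, pi_c=0.4, pi_disc=0.1, n_per_arm=100,
              label="benefit")
cfg = DesignConfig(n_total=100)  # classical rules, one interim at n=50

result = run_trial(sc, cfg, uninformative_priors(), seed=0)

d = result.data.interim
print(f"interim counts: events T {d.events_t}/{d.n_t}, "
      f"C {d.events_c}/{d.n_c}, discontinuations {d.disc_t}/{d.n_t}")
ev = result.interim_decision.evidence
print(f"P(ARR < 0) = {ev['p_eff']:.4f}  (efficacy needs > {ev['phi_c1']:.3f})")
print(f"P(pi_disc < m) = {ev['p_disc']:.4f}")
print(f"interim decision: {result.interim_decision.action}")

if result.final_decision is not None:
    d = result.data.final
    ev = result.final_decision.evidence
    print(f"\nfinal counts: events T {d.events_t}/{d.n_t}, "
          f"C {d.events_c}/{d.n_c}")
    print(f"P(ARR < 0) = {ev['p_eff']:.4f}  "
          f"(declaration needs > {ev['final_prob']})")
    print(f"final decision: {result.final_decision.action}")
print("\n(ARR = pi_T - pi_C; a negative ARR means the treatment lowers "
      "the event rate, so large P(ARR < 0) is evidence of benefit)")
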