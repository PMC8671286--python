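"""Classify the three canonical parameter sets and print the finite-size
steady state.

The only parameter varied is the cross-link breaking rate kappa_m; the
closed-form regime parameter alpha_bar decides the fate of the aggregate.
"""

from p62agg import RateConstants, classify_regime

for kappa_m in (0.6, 0.93, 0.2):
    params = RateConstants(n=5, kappa1=1.0, kappa2=1.0, kappa3=1.0,
                           kappa_m1=1.0, kappa_m=kappa_m)
    report = classify_regime(params)
    line = f"kappa_m = {kappa_m:4}: alpha_bar = {report.alpha_bar:+.4f} -> {report.regime.value}"
    if report.steady_state is not None:
        ss = report.steady_state
        line += f", steady state (p, q, r) = ({ss.p:.4f}, {ss.q:.4f}, {ss.r:.4f})"
    print(line)

print()
print("alpha_bar in (0, 1) means a finite limiting size; >= 1 dissolution;")
print("<= 0 unbounded growth. The steady state is the predicted aggregate")
print("composition (one-hand bound, cross-links, oligomers) in scaled units.")
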