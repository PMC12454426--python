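"""Integrate the baseline game and watch the four strategies settle.

Builds the payoff tensor from the baseline parameter set, integrates the
replicator system from the uniform state (everyone undecided at 0.5), and
reports where each population ends up: x = government strict regulation,
y = hospital strong enforcement, z = pharma self-discipline, w = public
participation.
"""

from carbongame import baseline_parameters, build_payoff_tensor, detect_convergence, integrate

params = baseline_parameters()
tensor = build_payoff_tensor(params)
traj = integrate(tensor, (0.5, 0.5, 0.5, 0.5), horizon=100.0)

x, y, z, w = traj.final_state
print(f"final state at t=100: x={x:.4f} y={y:.4f} z={z:.4f} w={w:.4f}")

conv = detect_convergence(traj, tol=0.01)
print(f"limit vertex: {conv.vertex}, entered its 0.01-ball at t={conv.first_passage_time:.2f}")
print(
    "reading: the government regulates strictly (x=1), pharma self-disciplines (z=1) and the\n"
    "public participates (w=1), while hospitals settle on weak enforcement (y=0) because the\n"
    "baseline makes weak enforcement's net benefit exceed strong enforcement's."
)
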