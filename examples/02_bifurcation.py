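"""Transcritical branching of the feedback-only steady states.

Scans total Rabex-5 across the onset threshold with the feedback pathway
alone (sigma = 0). Below threshold the origin is the stable state and the
companion branch is negative (unphysical); at the threshold the branches
cross and exchange stability; above it the positive branch is the stable
one. No fold (saddle-node) ever appears, so the switch has no bistability
or hysteresis - the onset is sharp but reversible.
"""

from rab5feedback import KineticParameters, bifurcation_scan, find_steady_states, onset_threshold

params = KineticParameters(alpha=1, beta=1, gamma=1, lam=100, sigma=0.0, z_tot=10)
threshold = onset_threshold(params)
print("onset threshold:", threshold)

for x_tot in (threshold / 2, 2 * threshold):
    report = find_steady_states(params.replace(x_tot=x_tot))
    print(f"\nx_tot = {x_tot:g}:")
    for (z, x2), stab, phys in zip(report.states, report.stability, report.physical):
        tag = "" if phys else "  (unphysical)"
        print(f"  z = {z:8.4f}, x2 = {x2:8.4f}: {stab}{tag}")

diagram = bifurcation_scan(params, (threshold / 10, threshold * 10), 201)
print("\nscan across the threshold:")
print("  transcritical crossing located at x_tot =", round(diagram.crossing, 9))
print("  saddle-node (fold) detected:", diagram.saddle_node_detected)

# The crossing coincides with lam*beta/(gamma*alpha*z_tot) and the scan
# never finds two coexisting stable states: delayed onset, not bistability.
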