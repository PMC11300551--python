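"""Neutral-drift and strong-selection limits of the t = 1 reward cost.

As the selection intensity beta goes to 0 the cost tends to an exact
rational limit; as beta grows it tends to N^2 theta/(N-1) (incentive leaves
defection dominant), twice that on the knife edge delta + theta = 0, or
diverges when the incentive overturns the gap.
"""

import coopcost as cc

N, theta = 7, 1.0
scheme = cc.IncentiveScheme(cc.Kind.REWARD, theta, t=1)

print("weak selection (N = 3, equal start):")
for beta in (1e-2, 1e-4, 1e-6):
    val = cc.cost_t1(cc.donation_game(3), scheme, cc.EvolutionParams(3, beta))
    print(f"  beta = {beta:<8g} E = {val:.6f}")
print(f"  limit             E = {cc.neutral_drift_limit(3, theta):.6f}")

print(f"\nstrong selection (N = {N}, three payoff gaps):")
for delta in (-1.5, -1.0, -0.5):
    game = cc.ConstantGapGame(N, delta)
    val = cc.cost_t1(game, scheme, cc.EvolutionParams(N, 50.0))
    lim = cc.strong_selection_limit(N, theta, delta)
    tag = {(-1.5): "delta+theta < 0", (-1.0): "knife edge", (-0.5): "divergent"}[delta]
    print(f"  delta = {delta:<5} E(beta=50) = {val:12.4f}   limit = {lim:<10} ({tag})")

print()
print("With delta + theta < 0 a lone rewarded cooperator is still swiftly")
print("eliminated, so the institution pays for about N^2/(N-1) generations;")
print("on the knife edge the walk at the paid state is balanced and the")
print("sojourn doubles; beyond it the paid state is revisited endlessly.")
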