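"""Incentive cost under non-negligible mutation.

With mutation no state is absorbing; the cost is accumulated until the
population first reaches a homogeneous state.  For t = 1 the cost falls as
the mutation rate rises (mutation shortens excursions through the paid
low-cooperation states), and the mu -> 0 values recover the absorbing-chain
cost.
"""

import coopcost as cc

game = cc.donation_game(6, B=2, c=1)
scheme = cc.IncentiveScheme(cc.Kind.REWARD, 1.0, t=1)

limit = cc.expected_cost(
    game, scheme, cc.EvolutionParams(6, 1.0, 0.0, cc.Start.ALLDEF)
)
print("start S_1 (one cooperator), beta = 1:")
for mu in (0.3, 0.1, 0.01, 1e-4):
    E = cc.expected_cost_general_mutation(
        game, scheme, cc.EvolutionParams(6, 1.0, mu), i_start=1
    )
    mc = cc.simulate_cost(
        game, scheme, cc.EvolutionParams(6, 1.0, mu), 1, 50_000, seed=7
    )
    print(f"  mu = {mu:<7g} E = {E:8.5f}   MC = {mc.mean_cost:8.5f} "
          f"+/- {mc.se_cost:.5f}")
print(f"  mu -> 0    E = {limit:8.5f}   (absorbing-chain value)")
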