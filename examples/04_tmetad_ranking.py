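"""t_META-D descriptor: ranking two systems by barrier height.

Runs constant-height (0.25 kcal/mol, no well-tempering) campaigns on two
double wells whose barriers differ by 2 k_BT and shows that the mean
unbinding time t_META-D orders them correctly — the qualitative use of
the descriptor.
"""

import numpy as np

import metadrt as m

for barrier_kt in (8.0, 10.0):
    res = m.run_campaign(
        m.CampaignConfig(
            system=m.double_well_fixture(barrier_kt),
            mode="tmetad",
            n_replicas=10,
            base_seed=42,
            max_time=2000.0,
        )
    )
    vals = res.summary.values
    print(
        f"barrier {barrier_kt:4.1f} kBT: t_META-D = "
        f"{np.mean(vals) * 1000:.1f} ± {np.std(vals, ddof=1) / np.sqrt(len(vals)) * 1000:.1f} ps"
        f"  (n = {res.n_effective})"
    )

print(
    "\nThe higher barrier needs more deposited potential before the system\n"
    "unbinds, so its mean t_META-D is longer; the descriptor ranks the two\n"
    "'compounds' in the order of their true kinetic stability."
)
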