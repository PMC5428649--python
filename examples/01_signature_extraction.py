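"""Extract an up/down fold-change signature from a replicated matrix.

Simulates a two-replicate treated-vs-DMSO microarray experiment with 50
planted up- and 50 planted down-regulated probes, then recovers them with
the standard FC >= 2 / FC <= 0.5 filter and writes the .grp tag files a
connectivity query consumes.
"""

from pathlib import Path

import herbconnect as hc

scenario = hc.make_expression_scenario(
    n_probes=1000, n_up=50, n_down=50,
    effect_multiplier=4.0, noise_sd=0.1, rng_seed=0)
matrix = hc.simulate_expression(scenario)

treated = hc.average_replicates(matrix, "treated")
control = hc.average_replicates(matrix, "DMSO")
fc = hc.fold_change(treated, control)
sig = hc.build_signature(fc, up_threshold=2.0, down_threshold=0.5,
                         source_label="example")

planted_up, planted_down = scenario.planted["treated"]
print(f"probes measured:        {len(fc.probe_ids)}")
print(f"up tags (FC >= 2):      {len(sig.up_tags)}  "
      f"({len(set(sig.up_tags) & planted_up)} of {len(planted_up)} planted)")
print(f"down tags (FC <= 0.5):  {len(sig.down_tags)}  "
      f"({len(set(sig.down_tags) & planted_down)} of {len(planted_down)} planted)")

out = Path("scratch/example_signature")
up_path, down_path = hc.write_signature(sig, out, "example")
print(f"wrote {up_path} and {down_path}")
print("Each .grp file lists one probe id per line; together they are the "
      "query signature for a connectivity search.")
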