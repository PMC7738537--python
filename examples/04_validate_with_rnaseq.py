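"""Validate called boundaries against RNA-Seq coverage with metagene profiles.

If calls are genuine transcript boundaries, average RNA-Seq depth in
transcript orientation steps up across TSSs and down across TTSs.  The
step statistic is the downstream/upstream mean-density ratio.
"""

import txends as tx

ds = tx.simulate(tx.SimulationParams(seed=7))
tss = tx.run_drnaseq_calling(ds.tap_plus, ds.tap_minus)
tts = tx.run_termseq_calling(ds.term)

tss_profile = tx.metaprofile(ds.coverage, tss, flank=100)
tts_profile = tx.metaprofile(ds.coverage, tts, flank=100)

print(f"TSS metaprofile over {tss_profile.n_sites} sites: "
      f"mean depth {tss_profile.mean_density[:100].mean():.2f} upstream -> "
      f"{tss_profile.mean_density[101:].mean():.2f} downstream")
print(f"TSS step ratio: {tx.step_statistic(tss_profile):.2f}  (> 1: density rises)")
print(f"TTS step ratio: {tx.step_statistic(tts_profile):.2f}  (< 1: density falls)")
# Ratios far from 1 in the expected direction confirm the called positions
# behave like transcript boundaries in an independent data type.
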