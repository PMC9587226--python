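"""Generate a small synthetic glycoproteomics data set and write every table.

The generator produces a proteome with topology/domain annotations, true
glycosites (some clustered into mucin-like patches), glycoPSM evidence with
TMT reporter intensities, a protein-abundance table, and an MS1 glycoform
peak table — all tied to a ground truth that downstream stages can be
checked against.
"""

from pathlib import Path

from glycopipe import io_tables
from glycopipe.simulate import (
    SimConfig,
    simulate_peak_table,
    simulate_proteome,
    simulate_sites_and_psms,
)

out = Path("scratch/example_dataset")
out.mkdir(parents=True, exist_ok=True)

config = SimConfig(seed=1, n_proteins=30, n_sites=100, patch_fraction=0.15,
                   effect_size=0.1, cv_noise=0.2, decoy_fraction=0.05)
proteome, features = simulate_proteome(config)
truth, psms = simulate_sites_and_psms(config, proteome, features)
peaks = simulate_peak_table(config, truth)

io_tables.write_fasta(out / "proteome.fasta", proteome)
io_tables.write_features(out / "features.tsv", features)
io_tables.write_psm_table(out / "psms.tsv", psms)
io_tables.write_peak_table(out / "peaks.tsv", peaks)
io_tables.write_quant_table(out / "protein_table.tsv", truth.protein_table)

targets = sum(1 for v in truth.site_targets.values() if v)
print(f"proteome:        {len(proteome)} proteins, {len(features)} features")
print(f"true glycosites: {len(truth.true_sites)} "
      f"({sum(len(c) for c in truth.patch_clusters)} in "
      f"{len(truth.patch_clusters)} clusters)")
print(f"knockout targets: {targets} sites assigned to exactly one knockout")
print(f"evidence:        {len(psms)} glycoPSMs, {len(peaks)} MS1 peaks "
      f"({len(truth.peak_decoys)} labeled decoys)")
print(f"written to {out}/")
# The cluster count is what the patch finder should rediscover; the targeted
# sites are what the differential stage should call isoform-specific.
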