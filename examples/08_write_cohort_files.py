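"""Export a synthetic cohort to the standard on-disk formats.

Writes MAF-like TSV and minimal VCF for variants, SEG-like TSV for
copy-number profiles, covariate TSV, and the karyotype table, into
an output directory.
"""

import sys
from pathlib import Path

from tgctk import io
from tgctk.cohort import CohortConfig, capture_intervals, generate_cohort
from tgctk.genome import default_genome

out = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("scratch/cohort_export")
out.mkdir(parents=True, exist_ok=True)

genome = default_genome()
samples, variants, profiles, truth = generate_cohort(CohortConfig(n_cases=10, seed=1))

io.write_maf(variants, out / "variants.maf.tsv")
io.write_vcf(variants, out / "variants.vcf")
io.write_seg(list(profiles.values()), out / "profiles.seg.tsv")
io.write_covariates(samples, out / "covariates.tsv")
io.write_bed(capture_intervals(genome), out / "capture.bed")
genome.to_tsv(out / "karyotype.tsv")
truth.exposures.to_csv(out / "truth_exposures.tsv", sep="\t")
truth.variant_truth.to_csv(out / "truth_variants.tsv", sep="\t", index=False)

for f in sorted(out.iterdir()):
    print(f"{f.name:<22} {f.stat().st_size / 1024:.1f} kB")
print(f"\n{len(samples)} samples, {len(variants)} variant records written to {out}/")
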