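#!/usr/bin/env python
"""Generate the synthetic study: genome, genes, genotypes, VCFs, reads, regions.

Emulates a 14-accession polyploid GBS panel (ploidies 6x/8x/12x) with known
ground truth.  Bulky raw files go to scratch/sim/; a one-row summary of what
was generated lands in results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from canegbs.reads import BarcodeSpec
from canegbs.simulate import (
    SimConfig,
    emit_caller_vcfs,
    simulate_allele_reads,
    simulate_fastq,
    simulate_genes,
    simulate_genome,
    simulate_genotypes,
    simulate_region_counts,
    write_genome,
    write_gff3,
)

ROOT = Path(__file__).resolve().parents[1]


def barcode(i: int) -> str:
    digits = []
    for _ in range(6):
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(reversed(digits))


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = SimConfig(rng_seed=args.seed)
    out = ROOT / "scratch" / "sim"
    out.mkdir(parents=True, exist_ok=True)

    genome, sites = simulate_genome(cfg)
    write_genome(genome, sites, out / "genome.fasta", out / "sites.bed")
    genes = simulate_genes(cfg, genome)
    write_gff3(genes, out / "genes.gff3", {s: len(q) for s, q in genome.items()})

    truth = simulate_genotypes(cfg, genome)
    simulate_allele_reads(truth, cfg)
    truth.write_tsv(out / "truth_genotypes.tsv")
    emit_caller_vcfs(truth, cfg, out)

    barcodes = [BarcodeSpec(s, barcode(i))
                for i, s in enumerate(sorted(cfg.ploidy))]
    with open(out / "barcodes.tsv", "w") as fh:
        for b in barcodes:
            fh.write(f"{b.sample_id}\t{b.barcode}\n")
    fastq_truth = simulate_fastq(cfg, barcodes, out / "reads.fastq")
    with open(out / "reads_truth.tsv", "w") as fh:
        for rid, s in fastq_truth.items():
            fh.write(f"{rid}\t{s}\n")

    matrix, region_truth = simulate_region_counts(cfg)
    matrix.to_tsv(out / "region_counts.tsv", out / "totals.tsv")
    region_truth.to_csv(out / "region_truth.tsv", sep="\t", index=False)

    summary = pd.DataFrame([{
        "seed": args.seed,
        "sequences": len(genome),
        "genome_bp": sum(len(s) for s in genome.values()),
        "planted_sites": sum(len(v) for v in sites.values()),
        "genes": len(genes),
        "loci": len(truth.loci),
        "accessions": len(cfg.ploidy),
        "reads": cfg.n_reads,
        "regions": cfg.n_regions,
        "pav_regions": int((region_truth.cls == "pav").sum()),
        "cnv_regions": int((region_truth.cls == "cnv").sum()),
    }])
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    summary.to_csv(res / "01_simulation_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"raw files under {out}")


if __name__ == "__main__":
    main()
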