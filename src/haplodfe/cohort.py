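"""Phased-cohort ingestion (VCF) and synthetic-cohort fixture generation.

Data mode takes a phased VCF plus a focal-variant table listing, per locus,
the focal coordinate, the derived allele, and the local mutation and
recombination rates; IBS records are computed among the derived-carrying
haplotypes only.  Fixture mode writes a fully synthetic phased cohort: per
locus a frequency-conditioned trajectory is drawn, n derived-carrying
haplotypes are simulated around the focal site (placed at the midpoint of
the region), and the cohort is emitted as an uncompressed VCF with one
contig per locus, together with the focal table and a truth file recording
the generating selection parameters.

Haplotypes not carrying the derived focal allele are outside the model (the
method ignores them); in fixtures they are written as reference-allele
carriers purely as placeholders.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .demography import DemographicModel, LocusParams, SampleConfig, SelectionParams
from .ibs import IBSData, WindowScheme, collect_ibs
from .coalescent import simulate_haplotypes
from .trajectories import sample_conditioned_trajectories

FOCAL_TABLE_COLUMNS = [
    "locus_id", "chrom", "pos", "ref", "alt", "derived_allele",
    "derived_count", "mean_r_up", "mean_r_down", "u",
]


def write_focal_table(path: str, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_focal_table(path: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = set(FOCAL_TABLE_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"focal table lacks columns: {sorted(missing)}")
    return tab


def ingest_cohort(
    vcf_path: str,
    focal_table: pd.DataFrame | str,
    scheme: WindowScheme,
    mask_singletons: bool = False,
    warn=warnings.warn,
) -> IBSData:
    """Compute both-direction IBS records for every focal variant in a
    phased cohort VCF.

    Haplotypes carrying the derived allele at the focal position are
    extracted; flanking sites within the last window boundary on each side
    enter the pairwise comparison; a site where either haplotype of a pair
    is unphased raises, and loci with insufficient flank on the contig or
    fewer than two derived haplotypes are excluded with a warning.
    """
    if isinstance(focal_table, str):
        focal_table = read_focal_table(focal_table)
    span = scheme.span
    vcf = pysam.VariantFile(vcf_path)
    contig_len = {name: c.length for name, c in vcf.header.contigs.items()}
    by_chrom: dict[str, list] = {}
    for rec in vcf:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    loci, ids, info_rows = [], [], []
    for _, row in focal_table.iterrows():
        locus_id = row["locus_id"]
        chrom, pos = str(row["chrom"]), int(row["pos"])
        clen = contig_len.get(chrom)
        if clen is not None and (pos - span < 1 or pos + span > clen):
            warn(f"locus {locus_id}: flank of {span:g} bp exceeds contig"
                 f" {chrom}, excluded")
            continue
        recs = by_chrom.get(chrom, [])
        focal = next((r for r in recs if r.pos == pos), None)
        if focal is None:
            raise ValueError(f"locus {locus_id}: focal variant {chrom}:{pos} "
                             "absent from the VCF")
        derived = str(row["derived_allele"])
        alleles = focal.alleles
        if derived not in alleles:
            raise ValueError(f"locus {locus_id}: derived allele {derived} not "
                             f"among {alleles} at {chrom}:{pos}")
        d_idx = alleles.index(derived)
        carriers = []  # (sample_name, haplotype_index)
        for name, call in focal.samples.items():
            gt = call["GT"]
            if None in gt:
                continue
            if len(gt) > 1 and not call.phased:
                raise ValueError(
                    f"locus {locus_id}: unphased genotype for sample {name} "
                    f"at {chrom}:{pos}")
            for hap_i, allele in enumerate(gt):
                if allele == d_idx:
                    carriers.append((name, hap_i))
        if len(carriers) < 2:
            warn(f"locus {locus_id}: fewer than 2 derived haplotypes, skipped")
            continue
        positions, rows_mat = [], []
        for rec in recs:
            if rec.pos == pos or not (pos - span <= rec.pos <= pos + span):
                continue
            hap_alleles = []
            for name, hap_i in carriers:
                call = rec.samples[name]
                gt = call["GT"]
                if None in gt:
                    hap_alleles = None
                    break
                if len(gt) > 1 and not call.phased:
                    raise ValueError(
                        f"locus {locus_id}: unphased genotype for sample "
                        f"{name} at {chrom}:{rec.pos}")
                hap_alleles.append(0 if gt[hap_i] == 0 else 1)
            if hap_alleles is None:
                continue  # missing genotype: site non-informative, skipped
            if sum(hap_alleles) > 0:
                positions.append(float(rec.pos - pos))
                rows_mat.append(hap_alleles)
        matrix = (np.asarray(rows_mat, dtype=np.int8)
                  if rows_mat else np.zeros((0, len(carriers)), dtype=np.int8))
        loci.append((np.asarray(positions), matrix, 0.0))
        ids.append(locus_id)
        info_rows.append({"locus_id": locus_id, "n": len(carriers),
                          "r": 0.5 * (float(row["mean_r_up"]) + float(row["mean_r_down"])),
                          "u": float(row["u"])})
    data = collect_ibs(loci, scheme, directions=("up", "down"),
                       mask_singletons=mask_singletons, locus_ids=ids, warn=warn)
    info = pd.DataFrame(info_rows).set_index("locus_id") if info_rows else None
    data.locus_info = info
    return data


def generate_fixture(
    out_prefix: str,
    demography: DemographicModel,
    selection_or_sampler,
    sample: SampleConfig,
    locus: LocusParams,
    A: int,
    seed: int = 0,
    theta_prf: float = 100.0,
) -> tuple[str, str, str]:
    """Write a synthetic phased cohort: VCF, focal table and truth JSON.

    ``selection_or_sampler`` is either a :class:`SelectionParams` (all loci
    share one 4Ns) or a callable ``(rng) -> SelectionParams`` drawing one
    per locus (a DFE).  The focal site is placed at the midpoint of each
    locus's region; each locus becomes its own contig.  Returns the three
    output paths.
    """
    rng = np.random.default_rng(seed)
    vcf_path = f"{out_prefix}.vcf"
    table_path = f"{out_prefix}.focal.tsv"
    truth_path = f"{out_prefix}.truth.json"
    n = sample.n
    n_samples = sample.S // 2
    sample_names = [f"S{i:05d}" for i in range(n_samples)]

    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=PASS,Description="All filters passed">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for a in range(A):
        header.contigs.add(f"locus{a:04d}", length=int(locus.length) + 2)
    for name in sample_names:
        header.add_sample(name)

    focal_rows, truth = [], []
    with pysam.VariantFile(vcf_path, "w", header=header) as out:
        for a in range(A):
            if isinstance(selection_or_sampler, SelectionParams):
                sel = selection_or_sampler
            else:
                sel = selection_or_sampler(rng)
            trajs = sample_conditioned_trajectories(
                demography, sel, theta_prf, sample, 1,
                seed=int(rng.integers(2**31)))
            tr = trajs[0]
            hs = simulate_haplotypes(tr, demography, locus, n,
                                     int(rng.integers(2**31)))
            # place the n derived haplotypes on the first chromosomes of the
            # cohort; the rest are reference placeholders
            carrier_hap = [(i // 2, i % 2) for i in range(n)]
            chrom = f"locus{a:04d}"
            focal_bp = int(math.floor(locus.focal_pos)) + 1
            sites = [(focal_bp, None)]
            for p, col in zip(hs.positions, range(hs.n_sites)):
                sites.append((int(math.floor(p)) + 1, col))
            sites.sort()
            for bp, col in sites:
                rec = out.new_record(contig=chrom, start=bp - 1,
                                     alleles=("A", "T"))
                for si, name in enumerate(sample_names):
                    alleles = [0, 0]
                    for hap_j, (smp, hap_i) in enumerate(carrier_hap):
                        if smp == si:
                            if col is None:
                                alleles[hap_i] = 1
                            else:
                                alleles[hap_i] = int(hs.matrix[col, hap_j])
                    rec.samples[name]["GT"] = tuple(alleles)
                    rec.samples[name].phased = True
                out.write(rec)
            focal_rows.append({
                "locus_id": chrom, "chrom": chrom, "pos": focal_bp,
                "ref": "A", "alt": "T", "derived_allele": "T",
                "derived_count": tr.final_sample_count,
                "mean_r_up": locus.r, "mean_r_down": locus.r, "u": locus.u,
            })
            truth.append({"locus_id": chrom, "gamma": sel.gamma,
                          "dominance": sel.dominance,
                          "age": tr.age, "final_count": tr.final_count})
    write_focal_table(table_path, pd.DataFrame(
        focal_rows, columns=FOCAL_TABLE_COLUMNS))
    with open(truth_path, "w") as fh:
        json.dump({"demography": demography.label, "S": sample.S,
                   "f": sample.f, "n": n, "loci": truth}, fh, indent=1)
    return vcf_path, table_path, truth_path
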