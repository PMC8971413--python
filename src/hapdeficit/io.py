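"""File formats: phased VCF 4.2, pedigree/trait/truth tables, reports.

Phased genotypes travel as VCF 4.2 with '|'-separated GT fields and a
per-site ``CM`` INFO tag carrying the genetic-map position; pedigree and
trait tables are tab-separated. Reading uses cyvcf2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .prioritize import CandidateVariant
from .simulate import PhasedGenotypeMatrix, TruthRecord, SimConfig, resolve_mgs

_BASES = ("A", "G")


def write_phased_vcf(genotypes: PhasedGenotypeMatrix, path) -> None:
    path = Path(path)
    snps = genotypes.snps
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hapdeficit\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,'
                 'Description="Genetic map position in cM">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in snps.groupby("chrom", sort=False):
            length = int(grp["pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.animal_ids) + "\n")
        haps = genotypes.haplotypes
        sep = "|" if genotypes.phase_known else "/"
        for j, (snp_id, chrom, pos, cm) in enumerate(
                snps[["snp_id", "chrom", "pos", "cM"]].itertuples(index=False)):
            gts = "\t".join(f"{haps[i, 0, j]}{sep}{haps[i, 1, j]}"
                            for i in range(haps.shape[0]))
            fh.write(f"{chrom}\t{pos}\t{snp_id}\t{_BASES[0]}\t{_BASES[1]}\t.\t"
                     f"PASS\tCM={cm:.6f}\tGT\t{gts}\n")


def read_phased_vcf(path) -> PhasedGenotypeMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, haps, phased = [], [], True
    for var in vcf:
        g = np.array(var.genotypes)  # (n, 3): allele0, allele1, phased flag
        phased = phased and bool(g[:, 2].all())
        haps.append(g[:, :2].astype(np.uint8))
        cm = var.INFO.get("CM")
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     float(cm) if cm is not None else var.POS / 1e6))
    vcf.close()
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "cM"])
    hap_arr = np.stack(haps, axis=-1)  # (n_animals, 2, n_snps)
    return PhasedGenotypeMatrix(animal_ids=samples, snps=snps,
                                haplotypes=hap_arr, phase_known=phased)


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    cols = ["animal_id", "sire_id", "dam_id", "sex", "birth_year", "genotyped"]
    pedigree[cols].to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t",
                      dtype={"animal_id": str, "sire_id": str, "dam_id": str})
    return resolve_mgs(ped)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits[["animal_id", "trait", "ebv", "reliability"]].to_csv(
        path, sep="\t", index=False)


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"animal_id": str})


def write_truth(truth: TruthRecord, path) -> None:
    carriers = truth.copies.index[truth.copies == 1]
    homs = truth.copies.index[truth.copies == 2]
    with Path(path).open("w") as fh:
        fh.write(f"chrom\t{truth.chrom}\n")
        fh.write(f"snp_start_index\t{truth.snp_start_index}\n")
        fh.write(f"snp_end_index\t{truth.snp_end_index}\n")
        fh.write(f"bp_start\t{truth.bp_start}\n")
        fh.write(f"bp_end\t{truth.bp_end}\n")
        fh.write(f"pattern\t{''.join(map(str, truth.pattern))}\n")
        fh.write(f"carriers\t{','.join(carriers)}\n")
        fh.write(f"homozygotes\t{','.join(homs)}\n")
        fh.write(f"trait_effects\t{json.dumps(truth.trait_effects)}\n")


def read_truth(path, config: SimConfig | None = None) -> TruthRecord:
    kv = {}
    with Path(path).open() as fh:
        for line in fh:
            key, _, val = line.rstrip("\n").partition("\t")
            kv[key] = val
    carriers = [a for a in kv["carriers"].split(",") if a]
    homs = [a for a in kv["homozygotes"].split(",") if a]
    copies = pd.Series(dtype=int)
    copies = pd.concat([pd.Series(1, index=carriers),
                        pd.Series(2, index=homs)]) if (carriers or homs) \
        else pd.Series(dtype=int)
    copies.index.name = "animal_id"
    return TruthRecord(
        chrom=kv["chrom"],
        snp_start_index=int(kv["snp_start_index"]),
        snp_end_index=int(kv["snp_end_index"]),
        bp_start=int(kv["bp_start"]), bp_end=int(kv["bp_end"]),
        pattern=np.frombuffer(kv["pattern"].encode(), dtype=np.uint8) - ord("0"),
        copies=copies, config=config or SimConfig(),
        trait_effects=json.loads(kv.get("trait_effects", "{}")))


def write_candidates_vcf(variants: list[CandidateVariant], sample_ids: list[str],
                         vcf_path, breeds_path=None) -> None:
    """Candidate variants as VCF 4.2 with a CSQ-style consequence tag, plus
    an optional sample-to-breed metadata table."""
    chroms = {}
    for v in variants:
        chroms[v.chrom] = max(chroms.get(v.chrom, 0), v.pos + 1)
    with Path(vcf_path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,'
                 'Description="consequence|gene|description|coding_change">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in chroms.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for v in variants:
            gts = []
            for d in v.dosages:
                if not np.isfinite(d):
                    gts.append("./.")
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            flt = "PASS" if v.hard_filter_pass else "lowqual"
            csq = "|".join([v.consequence, v.gene, v.description,
                            v.coding_change]).replace(" ", "_")
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{flt}\t"
                     f"CSQ={csq}\tGT\t" + "\t".join(gts) + "\n")
    if breeds_path is not None and variants:
        pd.DataFrame({"animal_id": sample_ids,
                      "breed": variants[0].breeds}).to_csv(
            breeds_path, sep="\t", index=False)


def read_candidates_vcf(vcf_path, breeds_path=None) -> tuple[list[CandidateVariant], list[str]]:
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if breeds_path is not None:
        meta = pd.read_csv(breeds_path, sep="\t", dtype=str).set_index("animal_id")
        breeds = meta.loc[samples, "breed"].to_numpy()
    else:
        breeds = np.array(["Holstein"] * len(samples))
    out = []
    for var in vcf:
        g = np.array(var.genotypes)
        dos = np.where(g[:, 0] < 0, np.nan,
                       g[:, :2].clip(min=0).sum(axis=1).astype(float))
        csq = var.INFO.get("CSQ") or "other|.|.|."
        parts = (csq.split("|") + ["."] * 4)[:4]
        out.append(CandidateVariant(
            chrom=var.CHROM, pos=var.POS, ref=var.REF,
            alt=var.ALT[0] if var.ALT else ".",
            consequence=parts[0], hard_filter_pass=var.FILTER is None,
            dosages=dos, breeds=breeds, gene=parts[1],
            description=parts[2].replace("_", " "),
            coding_change=parts[3]))
    vcf.close()
    return out, samples
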