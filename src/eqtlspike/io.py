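"""File formats: PLINK PED/MAP, expression/phenotype TSV, panel serialization.

PED rows follow the contest convention ``FID IID 0 0 0 PHENO a1 a2 ...`` with
nucleotide allele pairs; phenotype is PLINK-coded (1 = unaffected,
2 = affected, -9 = unset).  MAP rows are ``CHR SNP 0 BP``.  All writers format
floats with a fixed precision so identical (config, seed) runs are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Haplotype, PanelConfig, ReferencePanel, SnpDef
from .shuffle import SimulatedSubject, dose_matrix

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "write_expression",
    "write_phenotypes",
    "save_panel",
    "load_panel",
]

_PHENO = {None: "-9", False: "1", True: "2"}


def _chrom_of(panel: ReferencePanel, gene: str) -> int:
    # synthetic placement: one pseudo-chromosome per gene, in panel order
    return panel.genes.index(gene) + 1


def write_ped_map(subjects: list[SimulatedSubject], panel: ReferencePanel, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns both paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    with map_path.open("w") as fh:
        for snp in panel.snps:
            fh.write(f"{_chrom_of(panel, snp.gene)}\t{snp.snp_id}\t0\t{snp.position}\n")

    doses = dose_matrix(panel, subjects)
    # per-SNP genotype strings for doses 0/1/2
    geno = np.empty((len(panel.snps), 3), dtype=object)
    for j, snp in enumerate(panel.snps):
        ref, alt = snp.alleles
        geno[j] = [f"{ref} {ref}", f"{ref} {alt}", f"{alt} {alt}"]
    with ped_path.open("w") as fh:
        for i, subj in enumerate(subjects):
            cells = geno[np.arange(len(panel.snps)), doses[i]]
            fh.write(
                f"{subj.family_id} {subj.person_id} 0 0 0 {_PHENO[subj.affected]} " + " ".join(cells) + "\n"
            )
    return ped_path, map_path


def read_ped_map(prefix: str | Path, panel: ReferencePanel):
    """Read PED/MAP back into (doses DataFrame, phenotype Series, id DataFrame).

    Dose decoding uses the panel's (reference, alternate) allele definitions;
    the MAP is checked against the panel's SNP order.
    """
    prefix = Path(prefix)
    map_df = pd.read_csv(prefix.with_suffix(".map"), sep="\t", header=None, names=["CHR", "SNP", "CM", "BP"])
    snp_ids = [s.snp_id for s in panel.snps]
    if list(map_df["SNP"]) != snp_ids:
        raise ValueError("MAP SNP order does not match the panel")
    alt = {s.snp_id: s.alleles[1] for s in panel.snps}

    fids, iids, phenos, rows = [], [], [], []
    with prefix.with_suffix(".ped").open() as fh:
        for line in fh:
            parts = line.split()
            fids.append(parts[0])
            iids.append(parts[1])
            phenos.append(int(parts[5]))
            alleles = parts[6:]
            if len(alleles) != 2 * len(snp_ids):
                raise ValueError("PED genotype count does not match the MAP")
            a1 = alleles[0::2]
            a2 = alleles[1::2]
            rows.append([(a1[j] == alt[s]) + (a2[j] == alt[s]) for j, s in enumerate(snp_ids)])
    doses = pd.DataFrame(np.asarray(rows, dtype=np.int8), columns=snp_ids)
    ids = pd.DataFrame({"FID": fids, "IID": iids})
    return doses, pd.Series(phenos, name="PHENO"), ids


def write_expression(
    subjects: list[SimulatedSubject], panel: ReferencePanel, path: str | Path, stage: str = "final"
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    attr = {"final": "expr_final", "baseline": "expr_baseline", "network": "expr_network"}[stage]
    with path.open("w") as fh:
        fh.write("FID\tIID\t" + "\t".join(panel.genes) + "\n")
        for subj in subjects:
            vec = getattr(subj, attr)
            fh.write(f"{subj.family_id}\t{subj.person_id}\t" + "\t".join(f"{v:.6g}" for v in vec) + "\n")
    return path


def write_phenotypes(subjects: list[SimulatedSubject], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("FID\tIID\tAFFECTED\n")
        for subj in subjects:
            fh.write(f"{subj.family_id}\t{subj.person_id}\t{_PHENO[subj.affected]}\n")
    return path


# ---------------------------------------------------------------------------
# panel serialization (directory of plain-text files)


def save_panel(panel: ReferencePanel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with (directory / "snps.map").open("w") as fh:
        for snp in panel.snps:
            fh.write(
                f"{_chrom_of(panel, snp.gene)}\t{snp.snp_id}\t0\t{snp.position}"
                f"\t{snp.alleles[0]}\t{snp.alleles[1]}\t{snp.maf:.10g}\n"
            )

    with (directory / "haplotypes.tsv").open("w") as fh:
        fh.write("gene\thap\tpool_frequency\talleles\n")
        for gene in panel.genes:
            for k, hap in enumerate(panel.pools[gene]):
                fh.write(f"{gene}\t{k}\t{hap.pool_frequency:.12g}\t" + "".join(map(str, hap.alleles)) + "\n")

    meta = {
        "genes": panel.genes,
        "causal_snp": panel.causal_snp,
        "partial_effects": {f"{g}:{k}": v for (g, k), v in panel.partial_effects.items()},
        "genotypic_means": {f"{g}:{d}": v for (g, d), v in panel.genotypic_means.items()},
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in panel.config.__dict__.items()
        },
    }
    (directory / "panel.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    with (directory / "ref_expression.tsv").open("w") as fh:
        fh.write("\t".join(panel.genes) + "\n")
        for row in panel.ref_expression:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")
    return directory


def load_panel(directory: str | Path) -> ReferencePanel:
    directory = Path(directory)
    meta = json.loads((directory / "panel.json").read_text())
    cfg_raw = dict(meta["config"])
    cfg_raw["maf_beta_params"] = tuple(cfg_raw["maf_beta_params"])
    cfg_raw["snps_per_gene"] = tuple(cfg_raw["snps_per_gene"])
    cfg = PanelConfig(**cfg_raw)
    genes = list(meta["genes"])

    pools: dict[str, list[Haplotype]] = {g: [] for g in genes}
    hap_alleles: dict[str, np.ndarray] = {}
    pool_freqs: dict[str, np.ndarray] = {}
    raw: dict[str, list[tuple[float, np.ndarray]]] = {g: [] for g in genes}
    with (directory / "haplotypes.tsv").open() as fh:
        next(fh)
        for line in fh:
            gene, _k, freq, alleles = line.rstrip("\n").split("\t")
            raw[gene].append((float(freq), np.frombuffer(alleles.encode(), dtype=np.uint8) - ord("0")))
    for gene in genes:
        freqs = np.array([f for f, _ in raw[gene]])
        mat = np.vstack([a for _, a in raw[gene]]).astype(np.uint8)
        pool_freqs[gene] = freqs
        hap_alleles[gene] = mat
        pools[gene] = [
            Haplotype(gene=gene, alleles=mat[k].copy(), pool_frequency=float(freqs[k]))
            for k in range(mat.shape[0])
        ]

    snps: list[SnpDef] = []
    with (directory / "snps.map").open() as fh:
        for line in fh:
            chrom, snp_id, _cm, bp, ref, alt, maf = line.rstrip("\n").split("\t")
            snps.append(
                SnpDef(
                    snp_id=snp_id,
                    gene=genes[int(chrom) - 1],
                    position=int(bp),
                    alleles=(ref, alt),
                    maf=float(maf),
                )
            )

    ref_expression = np.loadtxt(directory / "ref_expression.tsv", skiprows=1)
    effects = np.zeros((len(genes), cfg.haplotypes_per_gene))
    partial_effects = {}
    for key, v in meta["partial_effects"].items():
        g, k = key.rsplit(":", 1)
        partial_effects[(g, int(k))] = v
        effects[genes.index(g), int(k)] = v
    genotypic_means = {}
    for key, v in meta["genotypic_means"].items():
        g, d = key.rsplit(":", 1)
        genotypic_means[(g, int(d))] = v

    ref_correlation = np.corrcoef(ref_expression, rowvar=False)
    np.fill_diagonal(ref_correlation, 1.0)
    return ReferencePanel(
        genes=genes,
        snps=snps,
        pools=pools,
        partial_effects=partial_effects,
        genotypic_means=genotypic_means,
        causal_snp=dict(meta["causal_snp"]),
        ref_expression=ref_expression,
        ref_correlation=ref_correlation,
        config=cfg,
        hap_alleles=hap_alleles,
        pool_freqs=pool_freqs,
        effects_array=effects,
        target_maf=None,
        ref_hap_counts={},
    )
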