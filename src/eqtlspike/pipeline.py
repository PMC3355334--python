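"""End-to-end pipeline: panel -> cohort -> spike-in -> disease -> scans -> release.

Presets mirror the contest's data releases and differ only in cohort size and
spike weight (descending across releases):

    practice_easy    1000 subjects, weight 4.0   (every spiked signal detectable)
    practice_medium  1000 subjects, weight 1.0
    contest          500 subjects,  weight 0.25  (titrated: some but not all detectable)
    full             1000 subjects, weight 0.25

A run writes PLINK PED/MAP genotypes, expression and phenotype TSVs, the full
single-locus table, the p < 0.05-filtered interaction table, a ground-truth
JSON (network genes, causal SNPs, weight), an attempt log, and a manifest with
SHA-256 checksums of every output — identical config + seed gives identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .association import default_shortlist, filter_report, single_locus_scan, sweep_interactions_to_file
from .disease import DiseaseModel
from .disease import assign_affection
from .network import (
    CONTEST_WEIGHT,
    PRACTICE_EASY_WEIGHT,
    PRACTICE_MEDIUM_WEIGHT,
    apply_network,
    build_default_network,
)
from .panel import PanelConfig, ReferencePanel, generate_reference_panel
from .shuffle import SimulationConfig, attempt_log, dose_matrix, simulate_cohort

__all__ = ["PRESETS", "RunManifest", "run_pipeline", "load_config", "simulate_release"]

PRESETS: dict[str, dict] = {
    "practice_easy": {"n_subjects": 1000, "spike_weight": PRACTICE_EASY_WEIGHT},
    "practice_medium": {"n_subjects": 1000, "spike_weight": PRACTICE_MEDIUM_WEIGHT},
    "contest": {"n_subjects": 500, "spike_weight": CONTEST_WEIGHT},
    "full": {"n_subjects": 1000, "spike_weight": CONTEST_WEIGHT},
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    panel_checksum: str
    outputs: dict[str, str]          # file name -> sha256
    timings: dict[str, float]
    attempts_total: int = 0

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def simulate_release(panel: ReferencePanel, sim: SimulationConfig, stage_seeds: tuple[int, int] = (0, 1)):
    """Cohort + spike-in + disease in one call.

    Returns (subjects, network spec, disease model).  ``stage_seeds`` seed the
    network sampling and the penetrance draws (the cohort uses ``sim.seed``).
    """
    subjects = simulate_cohort(panel, sim)
    spec = build_default_network(panel.genes, panel.causal_snp, weight=sim.spike_weight)
    apply_network(subjects, panel, spec, seed=stage_seeds[0])
    model = DiseaseModel(
        network_genes=spec.network_genes,
        threshold=sim.disease_threshold,
        penetrance_below=sim.penetrance_below,
    )
    assign_affection(subjects, panel, model, seed=stage_seeds[1])
    return subjects, spec, model


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> RunManifest:
    """Execute the full simulation and scan pipeline into ``out_dir``."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    preset = cfg.get("preset", "contest")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}")
    if seed is None:
        seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_kwargs = dict(PRESETS[preset])
    sim_kwargs.update(cfg.get("simulation", {}))
    panel_kwargs = dict(cfg.get("panel", {}))
    two_locus = bool(cfg.get("two_locus", True))
    shortlist_alpha = float(cfg.get("shortlist_alpha", 0.01))
    two_locus_full = bool(cfg.get("two_locus_full", False))

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in ss.spawn(3)]
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    panel = generate_reference_panel(PanelConfig(seed=seeds[0], **panel_kwargs))
    timings["panel"] = time.perf_counter() - t0

    sim = SimulationConfig(seed=seeds[1], **sim_kwargs)
    t0 = time.perf_counter()
    subjects = simulate_cohort(panel, sim)
    timings["cohort"] = time.perf_counter() - t0

    spec = build_default_network(panel.genes, panel.causal_snp, weight=sim.spike_weight)
    t0 = time.perf_counter()
    apply_network(subjects, panel, spec, seed=seeds[2])
    timings["spike"] = time.perf_counter() - t0

    model = DiseaseModel(
        network_genes=spec.network_genes,
        threshold=sim.disease_threshold,
        penetrance_below=sim.penetrance_below,
    )
    assign_affection(subjects, panel, model, seed=seeds[2] + 1)

    t0 = time.perf_counter()
    eio.write_ped_map(subjects, panel, out / "genotypes")
    eio.write_expression(subjects, panel, out / "expression.tsv")
    eio.write_phenotypes(subjects, out / "phenotypes.tsv")
    attempt_log(subjects).to_csv(out / "attempts.tsv", sep="\t", index=False, float_format="%.6g")
    eio.save_panel(panel, out / "panel")
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "network_genes": spec.network_genes,
                "causal_snp": {g: panel.causal_snp[g] for g in spec.network_genes},
                "weight": spec.weight,
                "disease_threshold": model.threshold,
                "penetrance_below": model.penetrance_below,
            },
            indent=1,
            sort_keys=True,
        )
    )
    timings["write"] = time.perf_counter() - t0

    snp_ids = [s.snp_id for s in panel.snps]
    positions = [s.position for s in panel.snps]
    chroms = [panel.genes.index(s.gene) + 1 for s in panel.snps]
    doses = dose_matrix(panel, subjects).astype(float)
    expr = np.vstack([s.expr_final for s in subjects])

    t0 = time.perf_counter()
    single = single_locus_scan(doses, expr, snp_ids=snp_ids, gene_names=panel.genes,
                               positions=positions, chromosomes=chroms)
    single_out = filter_report(single, mode="single")
    single_out.to_csv(out / "single_locus.qassoc", sep="\t", index=False, float_format="%.6g")
    timings["single_scan"] = time.perf_counter() - t0

    if two_locus:
        t0 = time.perf_counter()
        if two_locus_full:
            cols = list(range(len(snp_ids)))
        else:
            shortlist = default_shortlist(single, alpha=shortlist_alpha)
            col_of = {s: j for j, s in enumerate(snp_ids)}
            cols = [col_of[s] for s in shortlist]
        # streamed sweep: the p < 0.05 report filter is applied on the fly so
        # contest-scale shortlists (millions of pairs) stay memory-bounded
        sweep_interactions_to_file(
            doses[:, cols], expr, out / "interactions.epi",
            snp_ids=[snp_ids[c] for c in cols], gene_names=panel.genes,
            alpha=0.05, chunk_size=200_000,
        )
        timings["two_locus_scan"] = time.perf_counter() - t0

    outputs = {
        p.relative_to(out).as_posix(): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config={"preset": preset, **cfg},
        seed=seed,
        panel_checksum=outputs.get("panel/panel.json", ""),
        outputs=outputs,
        timings=timings,
        attempts_total=int(sum(s.attempts for s in subjects)),
    )
    manifest.save(out / "manifest.json")
    return manifest
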