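"""End-to-end orchestration: simulate -> filter -> AIMs -> classify ->
ancestry tracks -> bias -> FST/pi -> haplotype network -> resistance report.

Each stage writes its outputs as TSV/VCF under the run's output directory
and nothing ever mutates an earlier stage's files. A single global seed is
fanned out to per-stage child seeds (recorded in the manifest), so reruns
with the same configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import aims as aims_mod
from . import ancestry, divergence, haplonet, resistance
from .io import GenotypeMatrix, PanelAssignment, filter_variants, read_vcf, write_vcf
from .simulate import SimConfig, simulate_cohort, stack_samples, write_cohort_files

log = logging.getLogger("weedhyb")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``vcf`` + ``panels_tsv`` point at existing inputs, or
    ``simulate`` holds keyword arguments for :class:`SimConfig` and the run
    is simulation-backed. Threshold defaults are the conventional variant-
    filter and admixture-classification values.
    """

    out_dir: str = "weedhyb_run"
    seed: int = 0
    vcf: str | None = None
    panels_tsv: str | None = None
    simulate: dict[str, Any] = field(default_factory=dict)
    maf_min: float = 0.05
    hwe_p_min: float = 1e-7
    window_bp: int = 500_000
    step_bp: int = 250_000
    hmm_eps: float = 0.01
    hmm_rho: float = 1e-7
    focal_regions: list[list[Any]] = field(default_factory=list)
    q_matrix: str | None = None
    q_sample_order: str | None = None
    injury_tsv: str | None = None
    crop_panel_label: str = "crop"
    weed_panel_label: str = "weed"
    cohort_label: str = "contemporary"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict[str, Any]:
    """Execute every configured stage; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stage_seeds": {"simulate": seeds[0]},
        "config": asdict(config),
        "outputs": {},
        "stages": [],
    }
    chrom_lengths = None

    def _record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        log.info("stage %s complete (%d files)", stage, len(paths))

    # --- input stage: simulate or load -------------------------------------
    if config.vcf is None:
        sim_cfg = SimConfig(**{**config.simulate, "seed": seeds[0]})
        cohort, crop_gm, weed_gm, truth = simulate_cohort(sim_cfg)
        paths = write_cohort_files(cohort, crop_gm, weed_gm, truth,
                                   truth.sitemap, out)
        gm = stack_samples([cohort, crop_gm, weed_gm])
        panel = PanelAssignment(
            {**{s: config.cohort_label for s in cohort.sample_ids},
             **{s: config.crop_panel_label for s in crop_gm.sample_ids},
             **{s: config.weed_panel_label for s in weed_gm.sample_ids}})
        chrom_lengths = {c: sim_cfg.chrom_length_bp for c in sim_cfg.chrom_names}
        _record("simulate", *paths.values())
    else:
        gm = read_vcf(config.vcf)
        panel = PanelAssignment.read_tsv(config.panels_tsv)
        panel.validate_against(gm)
        manifest["stages"].append("load")

    # --- variant filters ----------------------------------------------------
    gm = filter_variants(gm, config.maf_min, config.hwe_p_min)
    filtered_vcf = out / "filtered.vcf"
    write_vcf(gm, filtered_vcf, chrom_lengths)
    _record("filter", filtered_vcf)

    crop_samples = panel.samples(config.crop_panel_label)
    weed_samples = panel.samples(config.weed_panel_label)
    cohort_samples = panel.samples(config.cohort_label)

    # --- AIM discovery and heterozygosity-decay dating ---------------------
    aim_set = aims_mod.identify_aims(
        gm.take_samples(crop_samples), gm.take_samples(weed_samples)
    )
    aims_path = out / "aims.tsv"
    aim_set.write_tsv(aims_path)
    rows = []
    for s in cohort_samples:
        coeff = aims_mod.supervised_ancestry(gm, s, aim_set, ("crop", "weed"))
        n_het, n_called, frac = aims_mod.aim_heterozygosity(gm, s, aim_set)
        est = aims_mod.estimate_generations(frac, n_called, n_het)
        rows.append(
            f"{s}\t{coeff['crop']:.4f}\t{coeff['weed']:.4f}\t{n_het}\t{n_called}"
            f"\t{frac:.5f}\t{est.g_hat:.3f}\t{est.ci[0]:.3f}\t{est.ci[1]:.3f}"
            f"\t{int(est.lower_bound_only)}"
        )
    coeff_path = out / "ancestry_coefficients.tsv"
    coeff_path.write_text(
        "sample\tcrop\tweed\tn_het\tn_called\thet_fraction\tg_hat\tg_lo\tg_hi"
        "\tlower_bound_only\n" + "\n".join(rows) + "\n"
    )
    _record("aims", aims_path, coeff_path)

    # --- optional Q-matrix classification ----------------------------------
    if config.q_matrix is not None:
        q = aims_mod.read_q_matrix(config.q_matrix, config.q_sample_order,
                                   aims_mod.DEFAULT_POPULATIONS)
        calls = aims_mod.classify_all(q)
        cls_path = out / "classification.tsv"
        calls.to_csv(cls_path, sep="\t", index=False)
        _record("classify", cls_path)

    # --- local ancestry tracks and bias table -------------------------------
    tracks = [
        ancestry.infer_tracks(gm, s, aim_set, config.hmm_eps, config.hmm_rho,
                              chrom_lengths)
        for s in cohort_samples
    ]
    tracks_path = out / "ancestry_tracks.bed"
    ancestry.write_tracks_bed(tracks, tracks_path)
    bias = ancestry.genome_bias(tracks, {s: config.cohort_label
                                         for s in cohort_samples})
    bias_path = out / "bias_table.tsv"
    bias.to_csv(bias_path, sep="\t")
    _record("tracks", tracks_path, bias_path)

    # --- windowed FST / pi and the dual comparison ---------------------------
    focal = [tuple(r) for r in config.focal_regions]
    paired, focal_tab = divergence.dual_comparison(
        gm, panel, config.cohort_label, config.crop_panel_label,
        config.weed_panel_label, config.window_bp, config.step_bp,
        focal, chrom_lengths,
    )
    fst_path = out / "fst_windows.tsv"
    paired.to_csv(fst_path, sep="\t", index=False)
    pi_tab = divergence.pi_windows(gm, panel, config.cohort_label,
                                   config.window_bp, config.step_bp,
                                   chrom_lengths)
    pi_path = out / "pi_windows.tsv"
    pi_tab.to_csv(pi_path, sep="\t", index=False)
    stage_paths = [fst_path, pi_path]
    if len(focal_tab):
        focal_path = out / "focal_windows.tsv"
        focal_tab.to_csv(focal_path, sep="\t", index=False)
        stage_paths.append(focal_path)
    _record("fst_pi", *stage_paths)

    # --- haplotype network around the first focal region --------------------
    if focal:
        chrom, start, end, name = focal[0]
        try:
            haps, positions, report = haplonet.extract_haplotypes(
                gm, (chrom, int(start), int(end))
            )
            net = haplonet.median_joining(haps)
            net.site_positions = positions
            haplonet.write_network_tsv(net, out / "haplonet_edges.tsv",
                                       out / "haplonet_nodes.tsv")
            _record("haplonet", out / "haplonet_edges.tsv",
                    out / "haplonet_nodes.tsv")
        except ValueError as exc:
            log.warning("haplonet stage skipped for %s: %s", name, exc)

    # --- resistance tabulation ----------------------------------------------
    if config.injury_tsv is not None:
        records = resistance.read_injury_tsv(config.injury_tsv)
        table = resistance.tabulate_resistance(records)
        res_path = out / "resistance_table.tsv"
        resistance.write_resistance_tsv(table, res_path)
        _record("resistance", res_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
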