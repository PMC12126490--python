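"""End-to-end runs: configuration, stage composition, and provenance.

``run_all`` executes simulate -> enrichment -> LTR profiles/differential
test -> bin correlation -> biophysics on one configuration and writes every
artifact plus a manifest of SHA-256 content hashes.  The same configuration
and seed always reproduce byte-identical artifacts, so the manifest doubles
as an integrity check for reruns.  A ``params.json`` record of every
resolved parameter (defaults included) is written alongside, sufficient to
re-run the pipeline exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bins as bins_mod
from . import biophys, enrich, io, ltr, synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "load_config"]


@dataclass
class RunConfig:
    """Flat-keyed configuration for a full pipeline run."""

    seed: int = 0
    outdir: str = "ervscape_run"
    # simulation
    n_families: int = 6
    loci_per_family: int = 30
    genome_length: int = 2_000_000
    input_mean: float = 20.0
    nb_dispersion: float = 10.0
    orphan_fraction: float = 0.3
    ltr_length: int = 350
    internal_length: int = 3000
    datasets: dict = field(
        default_factory=lambda: {"chipA": 10_000_000, "chipB": [12_000_000, 8_000_000]}
    )
    enrichment_factors: dict = field(
        default_factory=lambda: {
            "chipA": {"fam01": 6.0, "fam02": 3.0, "fam03": 1.0, "fam04": 1.0, "fam05": 1.0, "fam06": 1.0},
            "chipB": {"fam01": 1.0, "fam02": 1.0, "fam03": 1.0, "fam04": 4.0, "fam05": 2.0, "fam06": 1.0},
        }
    )
    # ltr stage
    window_up: int = 1500
    window_down: int = 8000
    profile_bin_size: int = 50
    atac_mean: float = 50.0
    atac_loss_factors: dict = field(default_factory=lambda: {"fam01": 0.25})
    # bins stage
    bin_width: int = 5000
    # biophysics stage
    kd: float = 0.5
    delta_i_max: float = 1.0
    p_total: float = 1.0
    titration_noise_sd: float = 0.01
    csp_tol_h: float = 0.15
    csp_tol_n: float = 1.0
    csp_alpha: float = biophys.DEFAULT_ALPHA
    frap_dip_depth: float = 0.25
    frap_dip_time: float = 15.0
    frap_noise_sd: float = 0.01
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Load a RunConfig from a flat YAML mapping; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig) -> dict:
    """Execute every stage on synthetic inputs; returns the artifact manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = synth.SimulationConfig(
        seed=config.seed,
        n_families=config.n_families,
        loci_per_family=config.loci_per_family,
        genome_length=config.genome_length,
        enrichment_factors=config.enrichment_factors,
        nb_dispersion=config.nb_dispersion,
        library_sizes=config.datasets,
        input_mean=config.input_mean,
        ltr_length=config.ltr_length,
        internal_length=config.internal_length,
        orphan_fraction=config.orphan_fraction,
    )
    stage = "simulate"
    try:
        annotation = synth.generate_repeat_annotation(sim)
        io.write_bed_annotation(annotation, outdir / "annotation.bed")
        counts = synth.simulate_count_table(annotation, sim)
        io.write_count_table(counts, outdir / "counts.tsv")

        stage = "enrich"
        matrix = enrich.run_enrichment_pipeline(annotation, counts)
        io.write_enrichment_matrix(matrix, outdir / "enrichment")
        dendro = enrich.cluster_matrix(matrix, axis="families").to_newick()
        (outdir / "enrichment.dendrogram.nwk").write_text(dendro + "\n")

        stage = "ltr"
        fam_map = synth.default_family_ltr_map(sim)
        anchors = ltr.dedup_ltrs(
            annotation,
            fam_map,
            window_up=config.window_up,
            window_down=config.window_down,
            bin_size=config.profile_bin_size,
        )
        coverage = synth.simulate_coverage(annotation, sim, sim.datasets[0])
        io.write_bedgraph(coverage, outdir / "coverage.bedgraph")
        profile = ltr.build_profile_matrix(coverage, anchors)
        profile.to_frame().to_csv(
            outdir / "profile_matrix.tsv", sep="\t", float_format=io.FLOAT_FORMAT,
            index_label="integration_id",
        )
        ltr.average_profile(profile).to_csv(
            outdir / "average_profile.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT
        )
        atac_a, atac_b = synth.simulate_atac_counts(
            anchors.anchors, config.atac_mean, config.nb_dispersion,
            config.atac_loss_factors, config.seed,
        )
        diff = ltr.ltr_differential_test(atac_a, atac_b)
        diff.to_csv(outdir / "ltr_differential.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)

        stage = "bins"
        cov_b = synth.simulate_coverage(annotation, sim, sim.datasets[-1])
        bt_a = bins_mod.bin_signal(coverage, config.bin_width, dataset="trackA")
        bt_b = bins_mod.bin_signal(cov_b, config.bin_width, dataset="trackB")
        rho, p = bins_mod.spearman_correlation(
            bt_a.signal["trackA"].to_numpy(), bt_b.signal["trackB"].to_numpy()
        )
        table = bt_a.to_frame()
        table["trackB"] = bt_b.signal["trackB"].to_numpy()
        table.to_csv(outdir / "bins.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)
        _write_json({"rho": rho, "p": p, "n": len(bt_a)}, outdir / "bin_correlation.json")

        stage = "biophys"
        ligand = np.linspace(0.0, 8.0 * config.p_total, 12)[1:]
        fits = []
        for rep in range(3):
            series = synth.simulate_titration(
                config.kd, config.delta_i_max, config.p_total, ligand,
                noise_sd=config.titration_noise_sd, seed=config.seed * 3 + rep,
            )
            io.write_titration(series, outdir / f"titration_rep{rep + 1}.tsv")
            fits.append(biophys.fit_binding_isotherm(series))
        report = biophys.summarize_replicates(fits)
        report["kd_per_replicate"] = [f.kd for f in fits]
        _write_json(report, outdir / "kd_fit.json")

        apo, bound = synth.simulate_peak_lists(
            30, shifted_set=(3, 7), disappeared_set=(11,), shift_magnitudes=(0.1, 0.5),
            seed=config.seed,
        )
        io.write_peak_list(apo, outdir / "peaks_apo.tsv")
        io.write_peak_list(bound, outdir / "peaks_bound.tsv")
        records = biophys.match_and_classify_peaks(
            apo, bound, tol_h=config.csp_tol_h, tol_n=config.csp_tol_n
        )
        biophys.csp_records_to_frame(records).to_csv(
            outdir / "csp.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT
        )

        curve = synth.simulate_frap_curve(
            config.frap_dip_depth, config.frap_dip_time,
            noise_sd=config.frap_noise_sd, seed=config.seed,
        )
        io.write_frap(curve, outdir / "frap.tsv")
        dips = biophys.frap_dip_depth(curve, probe_times=[1.0, config.frap_dip_time])
        _write_json({str(k): v for k, v in dips.items()}, outdir / "frap_dip.json")
    except Exception as exc:
        (outdir / "failed").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    params = asdict(config)
    _write_json(params, outdir / "params.json")
    artifacts = sorted(
        p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {p.name: _sha256(p) for p in artifacts}
    _write_json(manifest, outdir / "manifest.json")
    return manifest
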