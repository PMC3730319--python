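"""End-to-end orchestration: simulate -> preprocess -> select -> quantify ->
classify -> pathway network, with every intermediate serialized.

The configuration is a flat key-value mapping (YAML on disk); unknown keys
are rejected.  Every numeric artifact is written with a header line carrying
the SHA-256 hash of the producing configuration, so artifacts can always be
traced back to their parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import chemometrics, classify, pathway_net, quantify, spectra_prep, synthdata
from .errors import ConfigError
from .spectra import TIME_POINTS, Spectrum

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_per_group: int = 9
    cv: float = 0.10
    spacing: float = 0.001
    noise_sd: float = 2.5
    drift_amplitude: float = 20.0
    selection_threshold: float = 0.90
    alpha: float = 0.05
    svm_standardize: bool = True
    write_spectra: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_frame(df: pd.DataFrame, path: Path, cfg_hash: str, sep: str = ",", index=True):
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep=sep, index=index)


def read_artifact(path: Path, sep: str = ",", **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kw)


def run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute the full pipeline; returns artifact paths keyed by name.

    Stage failures propagate with the failing stage named; artifacts written
    before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    artifacts: dict[str, Path] = {}

    stage = "simulate"
    try:
        design = synthdata.StudyDesign(n_per_group=config.n_per_group, seed=config.seed)
        params = synthdata.RenderParams(
            spacing=config.spacing,
            noise_sd=config.noise_sd,
            drift_amplitude=config.drift_amplitude,
        )
        spectra, truth = synthdata.make_study(
            seed=config.seed, design=design, cv=config.cv, params=params
        )
        if config.write_spectra:
            specdir = outdir / "spectra"
            specdir.mkdir(exist_ok=True)
            for s in spectra:
                s.write(specdir / f"{s.sample_id}.txt")
            artifacts["spectra_dir"] = specdir
        truth_path = outdir / "ground_truth.csv"
        truth.to_csv(truth_path)
        artifacts["ground_truth"] = truth_path

        stage = "preprocess"
        binned = spectra_prep.bin_matrix(spectra)
        path = outdir / "binned.csv"
        _write_frame(binned.values, path, h)
        artifacts["binned"] = path

        stage = "select"
        model = chemometrics.fit_pca(binned, k=2)
        _write_frame(model.scores, outdir / "pca_scores.csv", h)
        _write_frame(model.loadings, outdir / "pca_loadings.csv", h)
        artifacts["pca_scores"] = outdir / "pca_scores.csv"
        mask48 = binned.meta["time_point"] == 48
        sub48 = spectra_prep.BinnedMatrix(
            binned.values.loc[mask48], binned.meta.loc[mask48], binned.edges
        )
        model48 = chemometrics.fit_pca(sub48, k=2)
        sel = chemometrics.select_regions(
            sub48, model48, threshold=config.selection_threshold, alpha=config.alpha
        )
        path = outdir / "selection.tsv"
        _write_frame(sel.report(), path, h, sep="\t", index=False)
        artifacts["selection"] = path

        stage = "quantify"
        conc = quantify.quantify_study(spectra)
        normed = quantify.normalize_total(conc)
        conc.to_csv(outdir / "concentrations.csv")
        normed.to_csv(outdir / "concentrations_normalized.csv")
        artifacts["concentrations"] = outdir / "concentrations.csv"

        stage = "foldchange"
        records = quantify.fold_changes(conc)
        path = outdir / "foldchanges.tsv"
        _write_frame(quantify.fold_change_report(records), path, h, sep="\t", index=False)
        artifacts["foldchanges"] = path
        _write_frame(quantify.heatmap_matrix(records, synthdata.PANEL), outdir / "heatmap.csv", h)
        artifacts["heatmap"] = outdir / "heatmap.csv"

        stage = "classify"
        results = [
            classify.evaluate_time_point(
                normed, tp, seed=config.seed, standardize=config.svm_standardize
            )
            for tp in TIME_POINTS
        ]
        path = outdir / "svm_metrics.tsv"
        _write_frame(classify.metrics_table(results), path, h, sep="\t", index=False)
        artifacts["svm_metrics"] = path

        stage = "pathways"
        fixdir = outdir / "pathway_fixture"
        fix = synthdata.make_pathway_fixture(fixdir)
        records_pw = pathway_net.parse_kgml(sorted(fix["kgml_dir"].glob("*.xml")))
        panel = [
            tuple(line.split("\t"))
            for line in fix["panel"].read_text().splitlines()[1:]
        ]
        genes = fix["genes"].read_text().split()
        gmap = pathway_net.GeneMap.read_tsv(fix["gene_map"])
        met_hits = pathway_net.map_metabolites(panel, records_pw)
        trans_hits = pathway_net.map_genes(genes, gmap, records_pw)
        met_p = {p for p, _ in met_hits}
        trans_p = {p for p, _ in trans_hits}
        path = outdir / "pathway_comparison.tsv"
        _write_frame(
            pathway_net.comparison_report(records_pw, met_p, trans_p), path, h,
            sep="\t", index=False,
        )
        artifacts["pathway_comparison"] = path
        g = pathway_net.build_graph(records_pw, met_hits, trans_hits)
        artifacts["graph"] = pathway_net.export_graph(g, outdir / "pathway_network.graphml")
        artifacts["graph_sif"] = pathway_net.export_graph(g, outdir / "pathway_network.sif")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return artifacts


def load_config(path: str | Path | None, seed: int | None = None) -> PipelineConfig:
    mapping: dict = {}
    if path is not None:
        import yaml

        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must be a flat key-value mapping")
        mapping.update(loaded)
    if seed is not None:
        mapping["seed"] = seed
    return PipelineConfig.from_mapping(mapping)


def read_spectra_dir(path: str | Path) -> list[Spectrum]:
    return [Spectrum.read(p) for p in sorted(Path(path).glob("*.txt"))]
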