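"""End-to-end orchestration: cohort -> (volumes -> RSN extraction) ->
per-subject Granger fits -> group statistics -> degree metrics -> report
bundle.

Every run writes, under ``output_dir``: per-group edge-statistic tables and
t matrices, the cross-group ANCOVA table, per-network mean-Z activation
table (when the voxel/ICA stage runs), degree profiles, a run log with all
parameters and seeds, and a JSON manifest of artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import extraction, graph, granger, io, stats, synthetic


class PipelineConfig(BaseModel):
    """Declarative configuration for :func:`run_pipeline`.

    Unknown keys are rejected by name; numeric parameters are validated
    against their documented ranges.
    """

    model_config = ConfigDict(extra="forbid")

    # paths
    input_dir: str | None = None  # cohort on disk; None -> simulate
    template_dir: str | None = None  # RSN templates; None -> ground-truth maps
    output_dir: str = "effconn_out"

    # extraction
    band_low_hz: float = 0.01
    band_high_hz: float = 0.10
    apply_bandpass: bool = False  # synthetic series are generated in-band
    pca_dims: int = 40
    n_components: int | str = 25  # or "mdl"
    z_threshold: float = 1.5
    tr_s: float = 2.0

    # causality model
    order: int = 1
    standardize: bool = True
    use_covariate_series: bool = True

    # statistics
    pattern_rule: str = "p<0.01"
    fdr_q: float = 0.05
    alpha: float = 0.01

    # simulation
    simulation_seed: int = 0
    ica_seed: int = 0
    T: int = synthetic.DEFAULT_T
    use_volumes: bool = False
    grid_shape: tuple[int, int, int] = (12, 12, 8)
    voxel_noise_sd: float = 0.5
    n_noise_components: int = 2

    @field_validator("alpha", "fdr_q")
    @classmethod
    def _prob(cls, v, info):
        if not (0 < v < 1):
            raise ValueError(f"{info.field_name}={v} must be in (0, 1)")
        return v

    @field_validator("z_threshold")
    @classmethod
    def _zpos(cls, v):
        if v <= 0:
            raise ValueError("z_threshold must be positive")
        return v

    @field_validator("pca_dims", "T")
    @classmethod
    def _pos(cls, v, info):
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1")
        return v

    @field_validator("order")
    @classmethod
    def _order(cls, v):
        if v != 1:
            raise ValueError("only order=1 is supported")
        return v

    @field_validator("n_components")
    @classmethod
    def _ncomp(cls, v):
        if isinstance(v, str):
            if v != "mdl":
                raise ValueError("n_components must be an integer or 'mdl'")
        elif v < 1:
            raise ValueError("n_components must be >= 1")
        return v

    @model_validator(mode="after")
    def _band(self):
        nyq = 0.5 / self.tr_s
        if not (0 < self.band_low_hz < self.band_high_hz < nyq):
            raise ValueError(
                f"band ({self.band_low_hz}, {self.band_high_hz}) must satisfy "
                f"0 < low < high < Nyquist ({nyq:g} Hz)"
            )
        return self

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Read a config from a JSON file with PipelineConfig keys."""
    with open(path) as fh:
        return PipelineConfig(**json.load(fh))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the artifact manifest (also written
    to ``output_dir/manifest.json``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": {}, "complete": False}

    def _register(name, path):
        manifest["artifacts"][name] = str(path)

    # ---- stage: cohort -----------------------------------------------------
    try:
        if config.input_dir:
            cohort = synthetic.read_cohort(config.input_dir)
        else:
            cohort = synthetic.default_cohort(seed=config.simulation_seed,
                                              T=config.T)
            synthetic.write_cohort(cohort, out / "cohort")
            _register("cohort", out / "cohort")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cohort", e) from e

    labels = list(cohort.node_labels)
    n_networks = len(labels)
    mean_z_table = None

    # ---- stage: extraction (optional voxel/ICA path) -----------------------
    try:
        if config.use_volumes:
            mixing = synthetic.make_mixing_model(
                grid_shape=config.grid_shape,
                n_signal=n_networks,
                n_noise=config.n_noise_components,
                voxel_noise_sd=config.voxel_noise_sd,
                seed=config.simulation_seed,
            )
            volumes = synthetic.simulate_voxel_volumes(
                cohort, mixing, seed=config.simulation_seed
            )
            vol_list = [volumes[s.subject_id] for s in cohort.subjects]
            mask = extraction.compute_mask(vol_list)
            flat = extraction.flatten_volumes(vol_list, mask)
            if config.apply_bandpass:
                flat = [
                    extraction.preprocess_timecourses(
                        f, config.tr_s,
                        band=(config.band_low_hz, config.band_high_hz),
                    )
                    for f in flat
                ]
            n_comp = config.n_components
            ica = extraction.GroupICA(
                n_components=n_comp,
                pca_dims=config.pca_dims,
                z_threshold=config.z_threshold,
                random_state=config.ica_seed,
            )
            subject_tcs = ica.fit_transform(flat)
            if config.template_dir:
                tpl_labels, tpl_maps = io.load_template_dir(config.template_dir)
                tpl_flat = np.stack([m[mask] for m in tpl_maps])
            else:
                tpl_labels = labels
                tpl_flat = mixing.flat_maps()[:n_networks][:, mask.ravel()]
            assignment = extraction.match_templates(
                ica.z_maps_, tpl_flat, tpl_labels
            )
            comp_idx = [assignment[lab][0] for lab in labels]
            signs = np.sign([assignment[lab][1] for lab in labels])
            signs[signs == 0] = 1.0
            network_tcs = [
                tc[:, comp_idx] * signs for tc in subject_tcs
            ]
            # per-subject mean-Z of active voxels for each network
            mz = np.full((len(cohort.subjects), n_networks), np.nan)
            for si, smaps in enumerate(ica.subject_maps_):
                for ni, ci in enumerate(comp_idx):
                    z, active = extraction.zscore_and_mask(
                        smaps[ci], config.z_threshold
                    )
                    if active.any():
                        mz[si, ni] = extraction.mean_active_z(z, active)
            mean_z_table = pd.DataFrame(mz, columns=labels)
            mean_z_table.insert(0, "subject_id",
                                [s.subject_id for s in cohort.subjects])
            mean_z_table.insert(1, "group",
                                [s.group for s in cohort.subjects])
            series_by_subject = {
                s.subject_id: pd.DataFrame(tc, columns=labels)
                for s, tc in zip(cohort.subjects, network_tcs)
            }
        else:
            series_by_subject = {
                s.subject_id: pd.DataFrame(s.timeseries, columns=labels)
                for s in cohort.subjects
            }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("extraction", e) from e

    # ---- stage: per-subject Granger fits -----------------------------------
    try:
        stacks: dict[str, np.ndarray] = {}
        ages: dict[str, np.ndarray] = {}
        sexes: dict[str, np.ndarray] = {}
        for group in cohort.groups:
            subs = cohort.by_group(group)
            mats = []
            for s in subs:
                Z = s.covariate_series if config.use_covariate_series else None
                fit = granger.fit_mvar(
                    series_by_subject[s.subject_id], Z,
                    standardize=config.standardize,
                )
                mats.append(fit.path_matrix())
            stacks[group] = np.stack(mats)
            ages[group] = np.array([s.age for s in subs])
            sexes[group] = np.array([s.sex for s in subs])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("gca", e) from e

    # ---- stage: group statistics -------------------------------------------
    try:
        profiles = {}
        for group in cohort.groups:
            table = stats.edge_one_sample_t(
                stacks[group], node_labels=labels, fdr_q=config.fdr_q
            )
            table.to_csv(out / f"{group}_edge_stats.csv", index=False)
            _register(f"edge_stats_{group}", out / f"{group}_edge_stats.csv")
            tmat = table.pivot(index="target", columns="source", values="t")
            tmat = tmat.reindex(index=labels, columns=labels)
            io.write_matrix_csv(tmat, out / f"{group}_t_matrix.csv")
            _register(f"t_matrix_{group}", out / f"{group}_t_matrix.csv")
            pattern = stats.group_pattern(
                table, rule=config.pattern_rule, node_labels=labels,
                group=group,
            )
            io.write_matrix_csv(pattern.sign_matrix(),
                                out / f"{group}_pattern.csv")
            _register(f"pattern_{group}", out / f"{group}_pattern.csv")
            profiles[group] = graph.degree_profile(pattern)
        ancova = stats.ancova_edge_table(stacks, ages, sexes, labels,
                                         fdr_q=config.fdr_q)
        ancova.to_csv(out / "ancova_edges.csv", index=False)
        _register("ancova_edges", out / "ancova_edges.csv")
        if mean_z_table is not None:
            mean_z_table.to_csv(out / "mean_z_subjects.csv", index=False)
            _register("mean_z_subjects", out / "mean_z_subjects.csv")
            groups_mz = {
                g: mean_z_table.loc[mean_z_table["group"] == g, labels]
                .to_numpy(float)
                for g in cohort.groups
            }
            mz_ancova = stats.ancova_value_table(groups_mz, ages, sexes, labels)
            mz_ancova.to_csv(out / "mean_z_ancova.csv", index=False)
            _register("mean_z_ancova", out / "mean_z_ancova.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stats", e) from e

    # ---- stage: degree metrics ---------------------------------------------
    try:
        degrees = graph.degree_table(profiles)
        degrees.to_csv(out / "degree_profiles.csv", index=False)
        _register("degree_profiles", out / "degree_profiles.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("graph", e) from e

    # ---- log + manifest ----------------------------------------------------
    from . import __version__

    log = {
        "package_version": __version__,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seeds": {"simulation": config.simulation_seed,
                  "ica": config.ica_seed},
        "n_subjects": len(cohort.subjects),
        "groups": {g: len(cohort.by_group(g)) for g in cohort.groups},
    }
    io.write_manifest(log, out / "run_log.json")
    _register("run_log", out / "run_log.json")
    manifest["complete"] = True
    io.write_manifest(manifest, out / "manifest.json")
    return manifest
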