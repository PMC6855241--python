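"""End-to-end orchestration of the analysis stages from one TOML config.

A run reads a conformational ensemble plus pocket selections and optional
energy/score tables, executes the enabled stages in dependency order
(clustering → DCC → per-frame networks → path tally → interface geometry →
MM-PBSA summaries → screening evaluation), and writes per-stage TSV outputs
plus a single JSON report echoing every parameter (defaults included, so
under-specified choices such as I_min and corr_min are always visible).
Identical config and seeds give a byte-identical report: no wall-clock
content is ever written.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_reps, energetics, geometry, psn_paths, screening_eval
from .structure_io import (
    ResidueSelection,
    flat_indices,
    read_energy_table,
    read_multimodel_pdb,
    read_score_table,
    select_residues,
)

__all__ = ["RunConfig", "run_config", "ConfigError", "DEFAULTS"]


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every bad field."""


DEFAULTS = {
    "cluster": {"enabled": False, "k": 8, "seed": 0, "n_init": 10,
                "selection": "", "atoms": "backbone"},
    "psn": {"distance_cutoff": 4.5, "i_min": 3.0, "normalization": "sqrt",
            "normalization_mode": "uniform", "include_adjacent": False},
    "paths": {"enabled": False, "corr_min": 0.3, "freq_min": 0.30,
              "superpose_dcc": True},
    "geometry": {"enabled": False, "n_sphere_points": 960,
                 "grid_spacing": 0.5, "inclusion_radius": 10.0,
                 "chain_a": "A", "chain_b": "B"},
    "energetics": {"enabled": False, "complex": "", "receptor": "",
                   "ligand": "", "delta": "", "hot_threshold": -1.0},
    "screening": {"enabled": False, "scores": "", "higher_better": False},
}


class RunConfig:
    """Validated pipeline configuration.

    Built from a TOML file or a nested dict with the sections of
    :data:`DEFAULTS` plus ``[inputs]`` (``ensemble``, ``source_pocket``,
    ``sink_pocket`` paths) and top-level ``outdir`` and ``seed``.
    """

    def __init__(self, raw: dict, base_dir: Path = Path(".")):
        self.raw = raw
        self.base_dir = Path(base_dir)
        self.outdir = Path(raw.get("outdir", "allopath_out"))
        if not self.outdir.is_absolute():
            self.outdir = self.base_dir / self.outdir
        self.seed = int(raw.get("seed", 0))
        self.inputs = dict(raw.get("inputs", {}))
        self.stages = {}
        for name, defaults in DEFAULTS.items():
            merged = dict(defaults)
            merged.update(raw.get(name, {}))
            self.stages[name] = merged
        self._validate()

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(raw, base_dir=path.parent)

    def _resolve(self, p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def _validate(self) -> None:
        errors = []
        needs_ensemble = (self.stages["cluster"]["enabled"]
                          or self.stages["paths"]["enabled"]
                          or self.stages["geometry"]["enabled"])
        if needs_ensemble:
            ens = self.inputs.get("ensemble", "")
            if not ens:
                errors.append("inputs.ensemble is required by an enabled stage")
            elif not self._resolve(ens).exists():
                errors.append(f"inputs.ensemble path not found: {ens}")
        if self.stages["paths"]["enabled"]:
            for key in ("source_pocket", "sink_pocket"):
                p = self.inputs.get(key, "")
                if not p:
                    errors.append(f"inputs.{key} is required by the paths stage")
                elif not self._resolve(p).exists():
                    errors.append(f"inputs.{key} path not found: {p}")
        if self.stages["energetics"]["enabled"]:
            e = self.stages["energetics"]
            if e["delta"]:
                if not self._resolve(e["delta"]).exists():
                    errors.append(f"energetics.delta path not found: {e['delta']}")
            elif not (e["complex"] and e["receptor"] and e["ligand"]):
                errors.append("energetics needs either a delta table or all of "
                              "complex/receptor/ligand tables")
            else:
                for key in ("complex", "receptor", "ligand"):
                    if not self._resolve(e[key]).exists():
                        errors.append(f"energetics.{key} path not found: {e[key]}")
        if self.stages["screening"]["enabled"]:
            s = self.stages["screening"]["scores"]
            if not s:
                errors.append("screening.scores is required")
            elif not self._resolve(s).exists():
                errors.append(f"screening.scores path not found: {s}")
        if errors:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))


def _reskey_str(key) -> str:
    chain, num, icode = key
    return f"{chain}:{num}{icode}"


def run_config(config: RunConfig | dict | str | Path) -> dict:
    """Execute the enabled stages and return (and write) the JSON report."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_toml(config)
    elif isinstance(config, dict):
        config = RunConfig(config)

    config.outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed,
                    "parameters": {k: dict(v) for k, v in config.stages.items()},
                    "stages": {}}

    ensemble = None
    if config.inputs.get("ensemble"):
        ensemble = read_multimodel_pdb(config._resolve(config.inputs["ensemble"]))
        report["inputs"] = {"ensemble": str(config.inputs["ensemble"]),
                            "n_frames": ensemble.n_frames,
                            "n_atoms": ensemble.n_atoms}

    psn_cfg = psn_paths.PSNConfig(
        distance_cutoff=config.stages["psn"]["distance_cutoff"],
        i_min=config.stages["psn"]["i_min"],
        normalization=config.stages["psn"]["normalization"],
        normalization_mode=config.stages["psn"]["normalization_mode"],
        include_adjacent=config.stages["psn"]["include_adjacent"])

    if config.stages["cluster"]["enabled"]:
        report["stages"]["cluster"] = _stage_cluster(config, ensemble)
    if config.stages["paths"]["enabled"]:
        report["stages"]["paths"] = _stage_paths(config, ensemble, psn_cfg)
    if config.stages["geometry"]["enabled"]:
        report["stages"]["geometry"] = _stage_geometry(config, ensemble)
    if config.stages["energetics"]["enabled"]:
        report["stages"]["energetics"] = _stage_energetics(config)
    if config.stages["screening"]["enabled"]:
        report["stages"]["screening"] = _stage_screening(config)

    out = config.outdir / "report.json"
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _load_pocket(config: RunConfig, key: str) -> ResidueSelection:
    return ResidueSelection.from_tsv(config._resolve(config.inputs[key]), label=key)


def _stage_cluster(config: RunConfig, ensemble) -> dict:
    p = config.stages["cluster"]
    if p["selection"]:
        sel = ResidueSelection.from_tsv(config._resolve(p["selection"]))
        groups = select_residues(ensemble.topology, sel, atoms=p["atoms"])
        idx = flat_indices(groups)
    else:
        idx = np.arange(ensemble.n_atoms)
    rmsd = cluster_reps.pairwise_rmsd(ensemble, idx)
    clustering = cluster_reps.kmeans_frames(rmsd, k=int(p["k"]),
                                            seed=int(p["seed"]),
                                            n_init=int(p["n_init"]))
    labels = pd.DataFrame({"frame": np.arange(ensemble.n_frames),
                           "cluster": clustering.labels})
    labels.to_csv(config.outdir / "cluster_labels.tsv", sep="\t", index=False)
    from .structure_io import write_multimodel_pdb
    write_multimodel_pdb(ensemble.subset_frames(clustering.medoids),
                         config.outdir / "medoids.pdb")
    return {"k": clustering.k,
            "populations": [round(float(x), 6) for x in clustering.populations],
            "medoid_frames": clustering.medoids.tolist()}


def _stage_paths(config: RunConfig, ensemble, psn_cfg) -> dict:
    p = config.stages["paths"]
    sources = _load_pocket(config, "source_pocket")
    sinks = _load_pocket(config, "sink_pocket")
    from .structure_io import residue_keys
    all_res = ResidueSelection.from_residue_keys(
        [(c, n) for c, n, _ in residue_keys(ensemble.topology)], label="all")
    ca = select_residues(ensemble.topology, all_res, atoms="calpha")
    dcc = psn_paths.dcc_matrix(ensemble, ca, superpose=bool(p["superpose_dcc"]))
    graphs = psn_paths.frame_graphs(ensemble, psn_cfg)
    tally = psn_paths.tally_paths(graphs, dcc, sources, sinks,
                                  corr_min=float(p["corr_min"]),
                                  freq_min=float(p["freq_min"]))
    rows = [{"path": "-".join(_reskey_str(r) for r in seq),
             "hops": len(seq) - 1, "frequency": round(freq, 6)}
            for seq, freq in sorted(tally.frequencies.items(),
                                    key=lambda sf: (-sf[1], sf[0]))]
    pd.DataFrame(rows, columns=["path", "hops", "frequency"]).to_csv(
        config.outdir / "paths.tsv", sep="\t", index=False)
    np.savetxt(config.outdir / "dcc.tsv", dcc.c, delimiter="\t", fmt="%.6f")
    return {"n_frames": tally.n_frames,
            "n_paths_total": len(tally.frequencies),
            "n_paths_frequent": tally.n_frequent,
            "freq_min": tally.freq_min,
            "top_path": ("-".join(_reskey_str(r) for r in tally.top)
                         if tally.top else None),
            "top_frequency": (round(tally.frequencies[tally.top], 6)
                              if tally.top else None)}


def _stage_geometry(config: RunConfig, ensemble) -> dict:
    p = config.stages["geometry"]
    table = geometry.RadiiTable()
    chain_a = np.array([i for i, r in enumerate(ensemble.topology)
                        if r.chain_id == p["chain_a"] and r.element.upper() != "H"])
    chain_b = np.array([i for i, r in enumerate(ensemble.topology)
                        if r.chain_id == p["chain_b"] and r.element.upper() != "H"])
    rows = []
    for f in range(ensemble.n_frames):
        frame = ensemble.coords[f]
        row = {"frame": f}
        if chain_a.size and chain_b.size:
            row["centroid_distance"] = round(
                geometry.centroid_distance(frame, chain_a, chain_b), 4)
            row["contact_area"] = round(
                geometry.contact_area(frame, ensemble.topology, chain_a, chain_b,
                                      table, n_sphere_points=int(p["n_sphere_points"])), 3)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(config.outdir / "geometry.tsv", sep="\t", index=False)
    out = {"n_frames": len(rows)}
    if "contact_area" in df.columns:
        out["mean_centroid_distance"] = round(float(df["centroid_distance"].mean()), 4)
        out["mean_contact_area"] = round(float(df["contact_area"].mean()), 3)
    return out


def _stage_energetics(config: RunConfig) -> dict:
    p = config.stages["energetics"]
    if p["delta"]:
        summary = energetics.binding_energy(
            read_energy_table(config._resolve(p["delta"])))
    else:
        summary = energetics.binding_energy(
            read_energy_table(config._resolve(p["complex"])),
            read_energy_table(config._resolve(p["receptor"])),
            read_energy_table(config._resolve(p["ligand"])))
    result = summary.as_dict()
    result["binding_mean"] = round(summary.binding_mean, 4)
    result["binding_sd"] = round(summary.binding_sd, 4)
    result["mean"] = {k: round(v, 4) for k, v in result["mean"].items()}
    result["sd"] = {k: round(v, 4) for k, v in result["sd"].items()}
    return result


def _stage_screening(config: RunConfig) -> dict:
    p = config.stages["screening"]
    scores = read_score_table(config._resolve(p["scores"]))
    curve = screening_eval.roc_points(scores, higher_better=bool(p["higher_better"]))
    value = screening_eval.auc(curve)
    pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr}).to_csv(
        config.outdir / "roc.tsv", sep="\t", index=False)
    return {"auc": round(value, 6), "n_active": curve.n_active,
            "n_decoy": curve.n_decoy}
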