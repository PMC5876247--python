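"""Configured, seeded end-to-end pipeline: simulate -> sensor statistics ->
feature extraction -> BMA inversion -> group conjunction.

A single :class:`PipelineConfig` drives every stage; the global seed is
expanded into independent per-stage substreams through a fixed counter scheme
(``numpy.random.SeedSequence([seed, stage_counter])``, counters listed in
``STAGE_COUNTERS``) so stages reproduce identically whether run together or
standalone on each other's output files.  Every output directory carries a
``manifest.json`` embedding the fully resolved configuration, the seed, and
SHA-256 hashes of all data files; identical config + seed yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .headmodel import build_head_model, build_montage, build_source_space, \
    compute_lead_field
from .simulate import ErpSet, generate_study
from .sensorstats import MassUnivariateAnova
from .inverse import BmaSourceModel, ISMap, PeakSpec, WindowSpec, extract_feature
from .conjunction import (binarize_lfdr, cluster_table, conjunction,
                          permutation_threshold)

__all__ = ["PipelineConfig", "run_pipeline", "STAGE_COUNTERS",
           "default_feature_specs", "simulate_stage", "sensor_stats_stage",
           "invert_stage", "conjoin_stage"]

log = logging.getLogger("erpsource")

#: Fixed counters of the per-stage seed substreams.
STAGE_COUNTERS = {"simulate": 0, "sensor_stats": 1, "invert": 2, "conjoin": 3}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic substream seed of a pipeline stage."""
    ss = np.random.SeedSequence([int(seed), STAGE_COUNTERS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class PipelineConfig:
    """Fully resolved pipeline parameters (YAML round-trippable)."""

    preset: str = "paper_like"
    seed: int = 0
    out_dir: str = "erpsource_out"
    # head / source space
    n_generators: int = 500
    n_compartments: int = 12
    # study design overrides (StudyDesign field name -> value)
    design_overrides: dict = field(default_factory=dict)
    # sensor statistics
    stats_q: float = 0.05
    # features
    n400_window_ms: tuple = (330.0, 440.0)
    peak_windows_ms: dict = field(default_factory=lambda: {
        "N170": (-1, 130.0, 200.0),
        "P200": (1, 180.0, 250.0),
        "N250": (-1, 230.0, 310.0),
    })
    #: components to invert (subset of N170/P200/N250/N400)
    features: tuple = ("N170", "P200", "N250", "N400")
    # inversion
    bma_max_size: int = 2
    occam_window: float = 0.05
    # conjunction
    lfdr_threshold: float = 0.2
    n_iter: int = 10000
    conj_q: float = 0.05
    cluster_min_value: float = 0.5

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["n400_window_ms"] = [float(v) for v in d["n400_window_ms"]]
        d["features"] = list(d["features"])
        d["peak_windows_ms"] = {k: [float(x) for x in v]
                                for k, v in d["peak_windows_ms"].items()}
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = str(source)
        if "\n" not in text:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        d = yaml.safe_load(text)
        d["n400_window_ms"] = tuple(d["n400_window_ms"])
        if "features" in d:
            d["features"] = tuple(d["features"])
        d["peak_windows_ms"] = {k: tuple(v) for k, v in d["peak_windows_ms"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("stats_q", "conj_q", "lfdr_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 <= self.occam_window < 1.0:
            raise ValueError(f"occam_window must be in [0, 1), got {self.occam_window}")
        if self.preset not in ("paper_like", "null"):
            raise ValueError(f"unknown preset {self.preset!r}")


def default_feature_specs(config: PipelineConfig) -> list:
    """Feature set inverted by the pipeline: per-task mismatch components."""
    specs = []
    if "N170" in config.features:
        pol, lo, hi = config.peak_windows_ms["N170"]
        specs.append(PeakSpec("N170", int(pol), lo, hi,
                              conditions=("intra_mismatch", "cross_mismatch")))
    for name in ("P200", "N250"):
        if name not in config.features:
            continue
        pol, lo, hi = config.peak_windows_ms[name]
        specs.append(PeakSpec(name, int(pol), lo, hi,
                              conditions=("intra_mismatch",)))
    if "N400" in config.features:
        lo, hi = config.n400_window_ms
        specs.append(WindowSpec("N400", lo, hi,
                                conditions=("intra_mismatch", "cross_mismatch")))
    return specs


def _write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def _rebuild_geometry(config: PipelineConfig):
    head = build_head_model()
    montage = build_montage("paper60")
    space = build_source_space(n_generators=config.n_generators,
                               n_compartments=config.n_compartments,
                               seed=config.seed)
    return head, montage, space


# ---------------------------------------------------------------------------
# Stages (each runnable standalone on the previous stage's files)
# ---------------------------------------------------------------------------

def simulate_stage(config: PipelineConfig, out: Path):
    """Generate the study and write the ErpSet plus planted ground truth."""
    t0 = time.time()
    try:
        erps, info = generate_study(config.preset, config.seed,
                                    design_overrides=config.design_overrides,
                                    n_generators=config.n_generators,
                                    n_compartments=config.n_compartments)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    out.mkdir(parents=True, exist_ok=True)
    eio.write_erpset(erps, out / "erps")
    _write_json({"preset": config.preset, "seed": config.seed,
                 "compartments": {k: int(v) for k, v in info["compartments"].items()},
                 "components": [c.name for c in info["components"]]},
                out / "ground_truth.json")
    config.to_yaml(out / "config.yaml")
    log.info("simulate: %.1fs", time.time() - t0)
    return erps, info


def sensor_stats_stage(config: PipelineConfig, erps: ErpSet, out: Path):
    """Mass-univariate ANOVA + FDR + post hoc maps; writes long-format maps."""
    t0 = time.time()
    try:
        res = MassUnivariateAnova(erps, q=config.stats_q).fit()
    except Exception as exc:
        raise RuntimeError(f"stage sensor_stats failed: {exc}") from exc
    stats_dir = out / "sensor_stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    for name, m in res.anova.items():
        m.to_frame().to_csv(stats_dir / f"anova_{name}.tsv", sep="\t",
                            index=False, float_format="%.10g")
        _write_json({"effect": m.effect, "df": list(m.df), "q": m.q,
                     "fdr_threshold": m.fdr_threshold,
                     "n_significant": m.n_significant},
                    stats_dir / f"anova_{name}.json")
    for m in res.posthoc:
        safe = m.effect.replace("@", "_at_")
        m.to_frame().to_csv(stats_dir / f"posthoc_{safe}.tsv", sep="\t",
                            index=False, float_format="%.10g")
    log.info("sensor_stats: %.1fs", time.time() - t0)
    return res


def invert_stage(config: PipelineConfig, erps: ErpSet, out: Path):
    """Extract component features and BMA-invert them per subject."""
    t0 = time.time()
    try:
        head, montage, space = _rebuild_geometry(config)
        lf = compute_lead_field(head, montage, space)
        inverter = BmaSourceModel(lf, space, max_size=config.bma_max_size,
                                  occam_window=config.occam_window)
        ismaps: dict = {}
        for spec in default_feature_specs(config):
            for f in extract_feature(erps, spec):
                ismaps.setdefault((spec.name, f.condition), []).append(
                    inverter.invert(f))
    except Exception as exc:
        raise RuntimeError(f"stage invert failed: {exc}") from exc
    inv_dir = out / "ismaps"
    inv_dir.mkdir(parents=True, exist_ok=True)
    for (comp, cond), maps in ismaps.items():
        eio.write_ismaps(maps, space, inv_dir / f"ismap_{comp}_{cond}.tsv")
    log.info("invert: %.1fs (%d maps)", time.time() - t0,
             sum(len(v) for v in ismaps.values()))
    return ismaps, space


def load_ismaps_dir(inv_dir: Path) -> dict:
    """Read ``ismap_*.tsv`` files back into per-subject ISMap lists."""
    ismaps: dict = {}
    for path in sorted(Path(inv_dir).glob("ismap_*.tsv")):
        df = eio.read_ismaps(path)
        for (comp, cond, subj), grp in df.groupby(
                ["component", "condition", "subject"], sort=True):
            grp = grp.sort_values("generator_id")
            ismaps.setdefault((comp, cond), []).append(ISMap(
                magnitudes=grp["magnitude"].to_numpy(float),
                subject=int(subj), condition=cond, component=comp))
    return ismaps


def conjoin_stage(config: PipelineConfig, ismaps: dict, space, out: Path):
    """Binarize, conjoin, permutation-threshold task contrasts, tabulate."""
    t0 = time.time()
    conj_dir = out / "conjunction"
    conj_dir.mkdir(parents=True, exist_ok=True)
    perm_seed = stage_seed(config.seed, "conjoin")
    conj_maps, diff_maps, tables = {}, {}, {}
    try:
        binmaps = {key: [binarize_lfdr(m, config.lfdr_threshold) for m in maps]
                   for key, maps in ismaps.items()}
        for key, bmaps in binmaps.items():
            cm = conjunction(bmaps)
            cm.component, cm.condition = key
            conj_maps[key] = cm
            tables[f"{key[0]}_{key[1]}"] = cluster_table(
                cm, space, config.cluster_min_value)
        for comp in ("N170", "N400"):
            a = binmaps.get((comp, "intra_mismatch"), [])
            b = binmaps.get((comp, "cross_mismatch"), [])
            common = sorted(set(m.subject for m in a) & set(m.subject for m in b))
            a = [m for m in a if m.subject in common]
            b = [m for m in b if m.subject in common]
            if not common:
                continue
            dm = permutation_threshold(a, b, n_iter=config.n_iter,
                                       q=config.conj_q, seed=perm_seed,
                                       contrast=f"{comp}: intra vs cross")
            diff_maps[comp] = dm
            tables[f"{comp}_diff"] = cluster_table(dm, space, min_value=0.0)
    except Exception as exc:
        raise RuntimeError(f"stage conjoin failed: {exc}") from exc
    for (comp, cond), cm in conj_maps.items():
        df = _conj_frame(cm.values, space)
        df.to_csv(conj_dir / f"conjunction_{comp}_{cond}.tsv", sep="\t",
                  index=False, float_format="%.17g")
    for comp, dm in diff_maps.items():
        df = _conj_frame(dm.values, space)
        df["p"] = dm.p_values
        df["significant"] = dm.mask
        df.to_csv(conj_dir / f"diff_{comp}.tsv", sep="\t", index=False,
                  float_format="%.17g")
    for name, tab in tables.items():
        tab.to_csv(conj_dir / f"clusters_{name}.tsv", sep="\t", index=False,
                   float_format="%.6g")
    log.info("conjoin: %.1fs", time.time() - t0)
    return binmaps, conj_maps, diff_maps, tables


def write_manifest(config: PipelineConfig, out: Path) -> dict:
    files = sorted(p for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "seed": config.seed,
        "stage_counters": STAGE_COUNTERS,
        "files": {str(p.relative_to(out)): eio.file_sha256(p) for p in files},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute all stages in order and write every output with a manifest.

    Returns a bundle with the ErpSet, StatMaps, ISMaps, conjunction maps,
    difference maps, cluster tables and the planted ground truth.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    erps, info = simulate_stage(config, out)
    stats_res = sensor_stats_stage(config, erps, out)
    ismaps, space = invert_stage(config, erps, out)
    binmaps, conj_maps, diff_maps, tables = conjoin_stage(config, ismaps,
                                                          space, out)
    manifest = write_manifest(config, out)
    log.info("pipeline complete: %.1fs", time.time() - t_start)
    return {"config": config, "erps": erps, "info": info,
            "sensor_stats": stats_res, "ismaps": ismaps, "space": space,
            "binary_maps": binmaps, "conjunction_maps": conj_maps,
            "diff_maps": diff_maps, "cluster_tables": tables,
            "manifest": manifest}


def _conj_frame(values, space):
    return pd.DataFrame({
        "generator_id": np.arange(space.n_generators),
        "compartment": [space.atlas[int(k)] for k in space.compartment_labels],
        "value": values,
    })
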