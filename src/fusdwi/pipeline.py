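"""End-to-end orchestration: simulate -> fit -> segment -> stats -> track.

Every stage writes its outputs plus a JSON provenance sidecar (stage name,
seed, configuration echo), and the whole run is deterministic under a fixed
global seed: the seed is expanded into per-stage substreams with
``numpy.random.SeedSequence`` so stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .exceptions import FusdwiError
from .phantom import Phantom, PhantomSpec, make_phantom
from .segmentation import extract_lesion, make_layers, mask_volume, select_cutoff
from .stats import build_layer_report
from .tensor import DiffusionTensorModel, compute_adc, compute_mdwi
from .tracking import TrackingParams, disruption_assay, save_streamlines_text, save_trk, seed_points, track

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("fusdwi")

_STAGE_NAMES = ("simulate", "fit", "segment", "stats", "track")


@dataclass
class PipelineConfig:
    """Everything a full run needs; see ``load_config`` for the TOML form."""

    out_dir: str = "fusdwi_out"
    seed: int = 0
    segmentation_fraction: float = 0.011
    noise_sigma: float = 0.0
    lesion_core_scale: float = 0.25
    small_grid: bool = False
    tracking: TrackingParams = field(default_factory=TrackingParams)
    seeds_per_voxel: int = 1
    nested_layers: bool = False
    log_level: str = "INFO"

    def phantom_spec(self, seed: int) -> PhantomSpec:
        from .phantom import small_phantom_spec

        kwargs = dict(
            noise_sigma=self.noise_sigma,
            lesion_core_scale=self.lesion_core_scale,
            seed=seed,
        )
        return small_phantom_spec(**kwargs) if self.small_grid else PhantomSpec(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path) -> PipelineConfig:
    """Read a TOML config; unknown keys are rejected."""
    raw = tomllib.loads(Path(path).read_text())
    tracking = TrackingParams(**raw.pop("tracking", {}))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FusdwiError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(tracking=tracking, **raw)


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    # keep stored seeds small (< 2**31) and reproducible
    return {
        name: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, c in zip(_STAGE_NAMES, children)
    }


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: PipelineConfig, phantom: Phantom | None = None) -> dict:
    """Run all stages, writing a report bundle under ``config.out_dir``.

    Returns a dict with the in-memory results (phantom, maps, layers, report,
    streamlines, assay) for programmatic use.  Rerunning with an identical
    config reproduces identical numeric outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    cfg_echo = config.to_dict()

    def fail(stage, exc):
        raise FusdwiError(f"stage '{stage}' failed: {exc}") from exc

    # -- simulate -----------------------------------------------------------
    try:
        if phantom is None:
            spec = config.phantom_spec(seeds["simulate"])
            phantom = make_phantom(spec)
        vs = phantom.pre.voxel_size
        fio.write_dwi(phantom.pre, out / "pre.nii.gz", out / "bvals", out / "bvecs")
        fio.write_dwi(phantom.post, out / "post.nii.gz")
        for name, mask in phantom.masks.items():
            fio.write_mask(mask, out / f"mask_{name}.nii.gz", vs)
        fio.write_provenance(out / "simulate.json", "simulate", seeds["simulate"], cfg_echo)
    except FusdwiError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        fail("simulate", exc)

    brain = phantom.masks["brain"]

    # -- fit ----------------------------------------------------------------
    try:
        maps = {}
        fits = {}
        for tp, dwi in (("pre", phantom.pre), ("post", phantom.post)):
            fit = DiffusionTensorModel(dwi, brain).fit()
            fits[tp] = fit
            m = fit.scalar_maps()
            m["ADC"] = compute_adc(dwi)
            m["MDWI"] = compute_mdwi(dwi)
            maps[tp] = m
            for kind, sm in m.items():
                fio.write_scalar_map(sm, out / f"{tp}_{kind.lower()}.nii.gz")
        fio.write_provenance(out / "fit.json", "fit", seeds["fit"], cfg_echo)
    except FusdwiError:
        raise
    except Exception as exc:
        fail("fit", exc)

    # -- segment ------------------------------------------------------------
    try:
        mdwi_post = maps["post"]["MDWI"]
        cutoff = select_cutoff(mdwi_post, brain, config.segmentation_fraction)
        region = extract_lesion(mdwi_post, cutoff, brain)
        layers = make_layers(region)
        rows = []
        for name, mask in [("region", layers.region), ("core", layers.core),
                           ("boundary_shell", layers.boundary_shell),
                           ("outer_shell", layers.outer_shell)]:
            fio.write_mask(mask, out / f"lesion_{name}.nii.gz", vs)
            rows.append({
                "mask_name": name,
                "voxel_count": int(mask.sum()),
                "volume_mm3": mask_volume(mask, vs),
                "cutoff_intensity": cutoff,
                "fraction_used": config.segmentation_fraction,
            })
        _write_tsv(pd.DataFrame(rows), out / "lesion_volumes.tsv")
        fio.write_provenance(out / "segment.json", "segment", seeds["segment"], cfg_echo)
    except FusdwiError:
        raise
    except Exception as exc:
        fail("segment", exc)

    # -- stats --------------------------------------------------------------
    try:
        report = build_layer_report(
            maps["pre"], maps["post"], layers, phantom.masks["reference"],
            nested=config.nested_layers,
        )
        _write_tsv(report.layer_table, out / "layer_report.tsv")
        _write_tsv(report.paired_tests, out / "paired_tests.tsv")
        _write_tsv(report.anova, out / "anova.tsv")
        _write_tsv(report.tukey, out / "tukey.tsv")
        fio.write_provenance(out / "stats.json", "stats", seeds["stats"], cfg_echo)
    except FusdwiError:
        raise
    except Exception as exc:
        fail("stats", exc)

    # -- track --------------------------------------------------------------
    try:
        seeds_mm = seed_points(
            phantom.masks["distal_seed"], config.seeds_per_voxel, seeds["track"], vs
        )
        streams = {}
        for tp in ("pre", "post"):
            s = track(seeds_mm, fits[tp], maps[tp]["FA"], config.tracking)
            streams[tp] = s
            save_trk(out / f"tracks_{tp}.trk", s, brain.shape, vs)
            save_streamlines_text(out / f"tracks_{tp}.txt", s)
        assay = disruption_assay(
            streams["pre"], streams["post"], phantom.masks["lesion"],
            phantom.masks["distal_seed"], phantom.masks["far_target"], vs,
        )
        _write_tsv(assay, out / "disruption_assay.tsv")
        fio.write_provenance(out / "track.json", "track", seeds["track"], cfg_echo)
    except FusdwiError:
        raise
    except Exception as exc:
        fail("track", exc)

    return {
        "phantom": phantom,
        "fits": fits,
        "maps": maps,
        "cutoff": cutoff,
        "layers": layers,
        "report": report,
        "streamlines": streams,
        "assay": assay,
        "out_dir": out,
    }
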