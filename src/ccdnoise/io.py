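"""Frame-stack I/O, run configuration and fixture generation.

Stacks travel as multi-page 32-bit-float TIFF files with a JSON sidecar
(same basename, ``.json``) holding exposure times, frame kinds, seeds and
-- for simulated data -- the ground-truth detector parameters.  The format
is deliberately plain so stacks stay inspectable with standard tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile
import yaml

from .frames import Frame
from .simulate import (
    BeamModel,
    DetectorModel,
    gaussian_kernel,
    inject_cosmic_rays,
    simulate_dark,
    simulate_frame,
)

__all__ = [
    "FrameStackContainer",
    "RunConfig",
    "read_stack",
    "write_stack",
    "generate_fixtures",
]


@dataclass
class FrameStackContainer:
    """Ordered frames plus the sidecar metadata record."""

    frames: list[Frame]
    sidecar: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty stack")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames in a stack must share one shape")

    @property
    def signal(self) -> list[Frame]:
        return [f for f in self.frames if f.kind == "signal"]

    @property
    def dark(self) -> list[Frame]:
        return [f for f in self.frames if f.kind == "dark"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(container: FrameStackContainer | Sequence[Frame], path) -> Path:
    """Write a stack as multi-page float32 TIFF plus JSON sidecar."""
    if not isinstance(container, FrameStackContainer):
        container = FrameStackContainer(list(container))
    path = Path(path)
    data = np.stack([f.data for f in container.frames]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    side = dict(container.sidecar)
    side.update(
        {
            "n_frames": len(container.frames),
            "shape": list(container.frames[0].shape),
            "exposures": [f.t_acq for f in container.frames],
            "kinds": [f.kind for f in container.frames],
            "seeds": [list(f.seed) if isinstance(f.seed, (tuple, list)) else f.seed for f in container.frames],
        }
    )
    _sidecar_path(path).write_text(json.dumps(side, indent=1))
    return path


def read_stack(path) -> FrameStackContainer:
    """Read a TIFF+JSON stack; raises descriptive errors on schema problems."""
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sc_path.name} next to {path.name}: stacks need "
            "their JSON metadata"
        )
    side = json.loads(sc_path.read_text())
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if not np.issubdtype(data.dtype, np.floating) and not np.issubdtype(
        data.dtype, np.integer
    ):
        raise TypeError(f"unsupported TIFF dtype {data.dtype}")
    if data.shape[0] != side.get("n_frames"):
        raise ValueError(
            f"sidecar says {side.get('n_frames')} frames, TIFF holds {data.shape[0]}"
        )
    if list(data.shape[1:]) != side.get("shape"):
        raise ValueError("frame shape mismatch between TIFF and sidecar")
    frames = [
        Frame(
            data[i].astype(float),
            side["exposures"][i],
            side["kinds"][i],
            tuple(side["seeds"][i]) if isinstance(side["seeds"][i], list) else side["seeds"][i],
        )
        for i in range(data.shape[0])
    ]
    return FrameStackContainer(frames, side)


# ---------------------------------------------------------------------------
# configuration


_DETECTOR_KEYS = {
    "shape",
    "beta_g",
    "g",
    "psf_fwhm",
    "sigma_qe",
    "dark_rate",
    "read_sigma",
    "row_sigma",
    "read_offset",
    "nonlin",
    "seed",
}
_BEAM_KEYS = {"s_el", "p", "sigma_tem"}
_PIPELINE_KEYS = {
    "cosmic_nsigma",
    "exclusion_radius",
    "bre_threshold",
    "bin_h",
    "bin_v",
    "eels_rows",
    "gainref_pairs",
}


@dataclass
class RunConfig:
    """Validated run configuration (detector / beam / pipeline / seed)."""

    detector: dict = field(default_factory=dict)
    beam: dict = field(default_factory=dict)
    pipeline: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, allowed, got in (
            ("detector", _DETECTOR_KEYS, self.detector),
            ("beam", _BEAM_KEYS, self.beam),
            ("pipeline", _PIPELINE_KEYS, self.pipeline),
        ):
            unknown = set(got) - allowed
            if unknown:
                raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"detector", "beam", "pipeline", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            detector=raw.get("detector", {}) or {},
            beam=raw.get("beam", {}) or {},
            pipeline=raw.get("pipeline", {}) or {},
            seed=int(raw.get("seed", 0)),
        )

    def detector_model(self) -> DetectorModel:
        kw = dict(self.detector)
        shape = tuple(kw.pop("shape", (256, 256)))
        if "nonlin" in kw:
            kw["nonlin"] = tuple(kw["nonlin"])
        return DetectorModel.reference(shape, seed=int(kw.pop("seed", self.seed)), **kw)

    def beam_model(self, det: DetectorModel, t_acq: float, target_counts: float = 7050.0) -> BeamModel:
        s_el = self.beam.get("s_el")
        if s_el is None:
            s_el = target_counts / det.g / t_acq
        p = float(self.beam.get("p", 0.0))
        sig = self.beam.get("sigma_tem")
        om = gaussian_kernel(float(sig), height_one=True) if sig else None
        return BeamModel.flat(float(s_el), p, om)


# ---------------------------------------------------------------------------
# fixtures


def generate_fixtures(config: RunConfig, out_dir) -> dict:
    """Emit the reference stacks every pipeline test runs on.

    Writes, under ``out_dir``: a dark series over exposures, a w-pair
    flat/dark gain-reference stack, an intensity ladder for the
    non-linearity fit, cosmic-ray-contaminated frames and a ZLP-like spike
    frame; ``manifest.json`` lists the files with the ground-truth
    parameters.  Two runs with the same seed are bit-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    det = config.detector_model()
    seed = config.seed
    t_ref = 0.84
    beam = config.beam_model(det, t_ref)

    manifest: dict[str, Any] = {
        "seed": seed,
        "ground_truth": {
            "g": det.g,
            "g_c": det.g_c,
            "beta_conv": float((det.psf_d.omega**2).sum()),
            "read_sigma": list(map(float, det.read_sigma)),
            "row_sigma": list(map(float, det.row_sigma)),
            "read_offset": list(map(float, det.read_offset)),
            "dark_rate": float(det.dark_rate_map.mean()),
            "nonlin": list(det.nonlin),
            "shape": list(det.shape),
        },
        "files": {},
    }

    # dark series over exposures
    exposures = [0.0, 0.5, 1.0, 2.0, 4.0]
    frames = []
    for j, t in enumerate(exposures):
        for r in range(2):
            frames.append(simulate_dark(det, t, (seed, 1, j, r)))
    manifest["files"]["dark_series"] = str(
        write_stack(FrameStackContainer(frames, {"role": "dark_series"}), out / "dark_series.tif")
    )

    # gain-reference stack
    w = int(config.pipeline.get("gainref_pairs", 0) or 16)
    frames = []
    for i in range(w):
        frames.append(simulate_frame(det, beam, t_ref, (seed, 2, i)))
        frames.append(simulate_dark(det, t_ref, (seed, 3, i)))
    manifest["files"]["gain_reference"] = str(
        write_stack(
            FrameStackContainer(frames, {"role": "gain_reference", "w": w}),
            out / "gain_reference.tif",
        )
    )

    # intensity ladder
    frames = []
    for z, t in enumerate(np.linspace(0.1, 2.0, 10)):
        frames.append(simulate_frame(det, beam, float(t), (seed, 4, z, 0)))
        frames.append(simulate_dark(det, float(t), (seed, 4, z, 1)))
    manifest["files"]["intensity_ladder"] = str(
        write_stack(
            FrameStackContainer(frames, {"role": "intensity_ladder"}),
            out / "intensity_ladder.tif",
        )
    )

    # cosmic-ray-contaminated frames
    frames = [
        inject_cosmic_rays(simulate_dark(det, 2.0, (seed, 5, i)), 36.5, (seed, 6, i))
        for i in range(3)
    ]
    manifest["files"]["cosmic"] = str(
        write_stack(FrameStackContainer(frames, {"role": "cosmic", "rate": 36.5}), out / "cosmic.tif")
    )

    # ZLP-like spike frame: a bright narrow horizontal band
    zlp = simulate_dark(det, 0.1, (seed, 7))
    rows, cols = det.shape
    band = np.exp(-((np.arange(rows) - rows / 2) ** 2) / (2 * 2.5**2))
    profile = np.exp(-((np.arange(cols) - cols / 2) ** 2) / (2 * (cols / 20) ** 2))
    zlp = zlp.copy_with(zlp.data + 3.0e4 * np.outer(band, profile))
    manifest["files"]["zlp"] = str(write_stack([zlp], out / "zlp.tif"))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
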