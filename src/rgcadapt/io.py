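"""HDF5 / JSON persistence for stimuli, responses and model parameters."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .ln_models import params_from_json, params_to_json
from .synthetic_data import SpikeResponse, Stimulus, StimulusGeometry, Trial

__all__ = [
    "save_stimulus",
    "load_stimulus",
    "save_responses",
    "load_responses",
    "save_params",
    "load_params",
]


def save_stimulus(h5: h5py.File | h5py.Group, stimulus: Stimulus, name: str = "stimulus"):
    """Write frames, trial ranges and geometry attributes under ``name``."""
    grp = h5.require_group(name)
    grp.create_dataset("frames", data=stimulus.frames, compression="gzip", compression_opts=1)
    trials = np.array(
        [[t.nonrep[0], t.nonrep[1], t.rep[0], t.rep[1]] for t in stimulus.trials],
        dtype=np.int64,
    )
    grp.create_dataset("trials", data=trials)
    g = stimulus.geometry
    grp.attrs.update(
        screen_height=g.screen_height,
        screen_width=g.screen_width,
        stim_pixel_factor=g.stim_pixel_factor,
        pixel_pitch=g.pixel_pitch,
        frame_rate=g.frame_rate,
        ensemble_label=stimulus.ensemble_label,
        pixel_size=stimulus.pixel_size,
        seed=-1 if stimulus.seed is None else stimulus.seed,
    )


def load_stimulus(h5: h5py.File | h5py.Group, name: str = "stimulus") -> Stimulus:
    grp = h5[name]
    a = grp.attrs
    geometry = StimulusGeometry(
        screen_height=int(a["screen_height"]),
        screen_width=int(a["screen_width"]),
        stim_pixel_factor=int(a["stim_pixel_factor"]),
        pixel_pitch=float(a["pixel_pitch"]),
        frame_rate=float(a["frame_rate"]),
    )
    trials = [
        Trial(nonrep=(int(r[0]), int(r[1])), rep=(int(r[2]), int(r[3])))
        for r in grp["trials"][()]
    ]
    seed = int(a["seed"])
    return Stimulus(
        frames=grp["frames"][()],
        geometry=geometry,
        trials=trials,
        ensemble_label=str(a["ensemble_label"]),
        pixel_size=int(a["pixel_size"]),
        seed=None if seed < 0 else seed,
    )


def save_responses(h5: h5py.File | h5py.Group, responses: list[SpikeResponse], name: str = "responses"):
    grp = h5.require_group(name)
    for resp in responses:
        cg = grp.require_group(resp.cell_id)
        counts = np.stack(resp.counts)  # trials are equal-length in this pipeline
        cg.create_dataset("counts", data=counts, compression="gzip", compression_opts=1)


def load_responses(h5: h5py.File | h5py.Group, name: str = "responses") -> list[SpikeResponse]:
    grp = h5[name]
    out = []
    for cell_id in sorted(grp.keys()):
        counts = grp[cell_id]["counts"][()]
        out.append(SpikeResponse(counts=[c for c in counts], cell_id=cell_id))
    return out


def save_params(path: Path, params):
    Path(path).write_text(params_to_json(params) + "\n")


def load_params(path: Path):
    return params_from_json(Path(path).read_text())
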