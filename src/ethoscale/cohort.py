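"""In-memory cohort containers and the HDF5 interchange schema.

A cohort is a collection of per-fish bout streams.  Each fish contributes a
posture tensor (bouts × frames × tail segments, radians), per-bout head
displacement vectors (mm, lab frame, start of one bout to start of the next),
the heading at each bout start (degrees), and inter-bout intervals (s), plus
metadata: sensory-context label and, for synthetic cohorts, the planted
phenotypic group and latent strategy labels.

HDF5 layout (written with ``track_times=False`` so identical content gives
byte-identical files)::

    /fish/<id>/bouts                posture tensor (n, frames, segments)
    /fish/<id>/kinematics/displacement   (n, 2) mm
    /fish/<id>/kinematics/heading        (n,) deg
    /fish/<id>/kinematics/ibi            (n,) s
    /fish/<id>/latent_labels        (n,) int, optional ground truth
    /fish/<id>  attrs: context, planted_group
    /           attrs: seed, schema_version
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class FishData:
    """One fish's bout stream."""

    posture: np.ndarray  # (n_bouts, frames, segments), radians
    displacement: np.ndarray  # (n_bouts, 2), mm
    heading: np.ndarray  # (n_bouts,), degrees at bout start
    ibi: np.ndarray  # (n_bouts,), seconds
    context: str = "default"
    planted_group: int | None = None
    latent_labels: np.ndarray | None = None

    @property
    def n_bouts(self) -> int:
        return self.posture.shape[0]

    def heading_change(self) -> np.ndarray:
        """Per-bout change in heading (deg), wrapped to (-180, 180]; length n_bouts-1."""
        dh = np.diff(self.heading)
        return (dh + 180.0) % 360.0 - 180.0

    def speed(self) -> np.ndarray:
        """Per-bout translational speed (mm/s): |displacement| / ibi."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.linalg.norm(self.displacement, axis=1) / self.ibi


@dataclass
class Cohort:
    fish: dict[str, FishData] = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_fish(self) -> int:
        return len(self.fish)

    @property
    def fish_ids(self) -> list[str]:
        return list(self.fish)

    def contexts(self) -> dict[str, list[str]]:
        """Map context label -> fish ids."""
        out: dict[str, list[str]] = {}
        for fid, f in self.fish.items():
            out.setdefault(f.context, []).append(fid)
        return out


def write_cohort(path, cohort: Cohort) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        if cohort.seed is not None:
            h5.attrs["seed"] = int(cohort.seed)
        grp = h5.create_group("fish")
        for fid in sorted(cohort.fish):
            f = cohort.fish[fid]
            g = grp.create_group(fid)
            g.attrs["context"] = f.context
            g.attrs["planted_group"] = -1 if f.planted_group is None else int(f.planted_group)
            g.create_dataset("bouts", data=f.posture, track_times=False)
            kin = g.create_group("kinematics")
            kin.create_dataset("displacement", data=f.displacement, track_times=False)
            kin.create_dataset("heading", data=f.heading, track_times=False)
            kin.create_dataset("ibi", data=f.ibi, track_times=False)
            if f.latent_labels is not None:
                g.create_dataset(
                    "latent_labels", data=np.asarray(f.latent_labels, dtype=np.int64),
                    track_times=False,
                )


def read_cohort_hdf5(path) -> Cohort:
    cohort = Cohort()
    n_skipped = 0
    with h5py.File(path, "r") as h5:
        if "fish" not in h5:
            raise ValueError(f"{path}: missing required group 'fish'")
        cohort.seed = int(h5.attrs["seed"]) if "seed" in h5.attrs else None
        for fid, g in h5["fish"].items():
            for req in ("bouts", "kinematics"):
                if req not in g:
                    raise ValueError(f"{path}: fish {fid!r} missing field {req!r}")
            for req in ("displacement", "heading", "ibi"):
                if req not in g["kinematics"]:
                    raise ValueError(f"{path}: fish {fid!r} missing field {req!r}")
            posture = g["bouts"][()]
            if posture.shape[0] == 0:
                n_skipped += 1
                continue
            pg = int(g.attrs.get("planted_group", -1))
            cohort.fish[fid] = FishData(
                posture=posture,
                displacement=g["kinematics/displacement"][()],
                heading=g["kinematics/heading"][()],
                ibi=g["kinematics/ibi"][()],
                context=str(g.attrs.get("context", "default")),
                planted_group=None if pg < 0 else pg,
                latent_labels=g["latent_labels"][()] if "latent_labels" in g else None,
            )
    if n_skipped:
        logger.warning("read_cohort: skipped %d fish with zero bouts", n_skipped)
    return cohort


#: required columns of the per-fish CSV dialect (one row per frame)
CSV_COLUMNS = ["time", *[f"angle{i}" for i in range(8)], "x", "y", "heading", "bout_id"]


def read_fish_csv(path, fish_id: str | None = None, context: str = "default") -> FishData:
    """Read one fish from a per-frame CSV (columns: time, angle0..7, x, y, heading, bout_id).

    Frames are grouped by ``bout_id``; bouts are padded/truncated to the modal
    frame count.  Displacement is taken head-start to head-start of consecutive
    bouts; the ibi is the gap between bout start times.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column {missing[0]!r}")
    angle_cols = [f"angle{i}" for i in range(8)]
    bouts, starts = [], []
    for _, sub in df.groupby("bout_id", sort=True):
        bouts.append(sub[angle_cols].to_numpy(float))
        starts.append(sub.iloc[0][["time", "x", "y", "heading"]].to_numpy(float))
    starts = np.asarray(starts)
    n_frames = int(np.median([b.shape[0] for b in bouts]))
    posture = np.zeros((len(bouts), n_frames, 8))
    for i, b in enumerate(bouts):
        m = min(n_frames, b.shape[0])
        posture[i, :m] = b[:m]
    displacement = np.zeros((len(bouts), 2))
    displacement[:-1] = np.diff(starts[:, 1:3], axis=0)
    ibi = np.ones(len(bouts))
    ibi[:-1] = np.diff(starts[:, 0])
    return FishData(
        posture=posture, displacement=displacement, heading=starts[:, 3],
        ibi=ibi, context=context,
    )
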