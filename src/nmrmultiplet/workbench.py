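"""I/O plumbing: spectrum tables, the dataset container, run manifests.

Real spectra enter as exported two-column numeric tables (position,
intensity) with the position unit declared on a comment line; datasets
travel in a single HDF5 container holding the intensity and label
matrices, per-segment metadata and the generating configuration as
embedded JSON, so a write-read round trip is lossless and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .simulate import LabeledDataset, SimulationConfig, SpectrumSegment

DATASET_FORMAT_VERSION = 1


@dataclass
class SpectrumTable:
    """A validated (position, intensity) table, ascending in Hz internally."""

    axis_hz: np.ndarray
    intensity: np.ndarray
    unit: str  # unit declared in the file ("ppm" or "hz")
    frequency_mhz: float | None = None
    flipped: bool = False  # True when the file was descending and got reversed

    def __len__(self) -> int:
        return len(self.axis_hz)


def read_spectrum_table(path, frequency_mhz: float | None = None) -> SpectrumTable:
    """Read a two-column spectrum table.

    The file holds numeric rows ``position intensity`` (whitespace,
    comma or tab separated).  Comment lines start with ``#``; one of
    them must declare the position unit, e.g. ``# unit: ppm`` or
    ``# unit: hz``.  ppm positions are converted to Hz with
    ``frequency_mhz`` (required in that case).  A descending axis is
    accepted and reversed, recorded in ``flipped``.
    """
    unit = None
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip().lower()
                if body.startswith("unit"):
                    unit = body.split(":", 1)[-1].strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1]), lineno))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric row {line!r}") from None
    if unit is None:
        raise ValueError(f"{path}: missing unit declaration ('# unit: ppm' or '# unit: hz')")
    if unit not in ("ppm", "hz"):
        raise ValueError(f"{path}: unknown position unit {unit!r}")
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least two data rows")

    pos = np.array([r[0] for r in rows])
    inten = np.array([r[1] for r in rows])
    d = np.diff(pos)
    if not (np.all(d > 0) or np.all(d < 0)):
        bad = rows[int(np.argmax(d * (1 if d[0] > 0 else -1) <= 0)) + 1][2]
        raise ValueError(f"{path}: non-monotone position axis near line {bad}")
    flipped = bool(d[0] < 0)
    if flipped:
        pos, inten = pos[::-1], inten[::-1]
    if unit == "ppm":
        if frequency_mhz is None:
            raise ValueError(f"{path}: ppm axis requires the spectrometer frequency (MHz)")
        pos = pos * frequency_mhz
    return SpectrumTable(
        axis_hz=pos, intensity=inten, unit=unit, frequency_mhz=frequency_mhz, flipped=flipped
    )


def read_peak_list(path) -> pd.DataFrame:
    """Expert peak list: TSV with header ``position_ppm amplitude linewidth_hz class``."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    required = {"position_ppm", "amplitude", "linewidth_hz", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: peak list is missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


def save_dataset(dataset: LabeledDataset, path) -> None:
    """Write a dataset to one HDF5 file (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = DATASET_FORMAT_VERSION
        f.create_dataset("intensity", data=dataset.intensity_matrix())
        f.create_dataset("labels", data=dataset.label_matrix())
        f.create_dataset(
            "split", data=np.array([s.encode() for s in dataset.split])
        )
        seg0 = dataset.segments[0]
        f.attrs["sweep_width_hz"] = seg0.sweep_width
        f.attrs["base_frequency_mhz"] = seg0.base_frequency
        f.attrs["provenance"] = json.dumps(dataset.provenance)
        f.attrs["segment_meta"] = json.dumps([s.meta for s in dataset.segments])


def load_dataset(path) -> LabeledDataset:
    """Read a dataset container, refusing unknown format versions."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != DATASET_FORMAT_VERSION:
            raise ValueError(
                f"{path}: dataset container version {version} not supported "
                f"(expected {DATASET_FORMAT_VERSION})"
            )
        intensity = f["intensity"][...]
        labels = f["labels"][...]
        split = [s.decode() for s in f["split"][...]]
        sweep = float(f.attrs["sweep_width_hz"])
        freq = float(f.attrs["base_frequency_mhz"])
        provenance = json.loads(f.attrs["provenance"])
        metas = json.loads(f.attrs["segment_meta"])
    n_points = intensity.shape[1]
    axis = np.arange(n_points) * (sweep / n_points)
    segments = [
        SpectrumSegment(
            axis=axis,
            intensity=intensity[i],
            labels=labels[i],
            sweep_width=sweep,
            base_frequency=freq,
            meta=metas[i],
        )
        for i in range(intensity.shape[0])
    ]
    return LabeledDataset(segments=segments, split=split, provenance=provenance)


# ---------------------------------------------------------------------------
# configs and manifests
# ---------------------------------------------------------------------------


def load_simulation_config(path) -> SimulationConfig:
    """Read a YAML/JSON key-value file mirroring :class:`SimulationConfig`."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI / pipeline run."""

    command: str
    config: dict
    seed: int | None
    inputs: dict
    outputs: dict
    tool_version: str
    started: float
    finished: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def new_manifest(command: str, config: dict, seed: int | None, inputs: dict | None = None) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        config=config,
        seed=seed,
        inputs=inputs or {},
        outputs={},
        tool_version=__version__,
        started=time.time(),
    )
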