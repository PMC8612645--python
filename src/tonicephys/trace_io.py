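"""Sweep data model and interchange I/O.

The package works on two kinds of raw traces: current-clamp voltage
responses to step-current families (IV protocols) and long voltage-clamp
holding-current recordings at -60 mV with timed drug epochs.  Both are
represented by :class:`Sweep`.  Units are fixed package-wide: seconds,
millivolts for voltages, picoamps for currents.  Readers never resample
or rescale.

Two self-describing on-disk layouts are supported:

* **interchange HDF5** -- one file per cell, one group per sweep holding
  ``samples``, ``stimulus``, scalar ``dt`` and an ``epochs`` table of
  (label, t_start, t_end) triples in seconds;
* **csv-dir** -- one directory per cell with per-sweep two-column CSVs
  (``t_s,value``), a parallel ``*.stim.csv`` for the command waveform and
  a JSON sidecar for metadata.

An NWB reader is available when :mod:`pynwb` is installed; its absence
does not affect the rest of the package.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import h5py
import numpy as np

__all__ = [
    "Sweep",
    "CellRecord",
    "PatientMeta",
    "FormatError",
    "ValidationError",
    "read_cell",
    "write_cell",
    "read_patient_table",
    "write_patient_table",
]

SIGNAL_KINDS = ("voltage", "current")

SEIZURE_HISTORY_LEVELS = ("none", "more_than_1y_ago", "within_1y")
DEXAMETHASONE_LEVELS = ("none", "at_surgery", "presurgery")
SEX_LEVELS = ("M", "F")
HEMISPHERE_LEVELS = ("left", "right")
LOBE_LEVELS = ("frontal", "temporal", "parietal", "occipital")
AXONAL_CLASSES = (
    "rosehip",
    "neurogliaform",
    "stalked",
    "L2-3",
    "other",
    "not_recovered",
)

PATIENT_TABLE_HEADER = [
    "patient_id",
    "age",
    "sex",
    "pathology",
    "cortical_area",
    "seizure_history",
    "dexamethasone",
    "levetiracetam",
    "hemisphere",
    "lobe",
]


class FormatError(ValueError):
    """Raised when a file is missing required metadata (dt, units, ...)."""


class ValidationError(ValueError):
    """Raised when parsed data violates a structural invariant."""


@dataclass
class Sweep:
    """One uniformly sampled trace plus its aligned stimulus command.

    ``samples`` are mV for ``signal_kind == "voltage"`` (current clamp)
    and pA for ``signal_kind == "current"`` (voltage clamp); ``stimulus``
    carries the complementary unit (pA command for current clamp, mV
    command for voltage clamp).
    """

    samples: np.ndarray
    dt: float
    signal_kind: str
    stimulus: np.ndarray
    epochs: list[tuple[str, float, float]] = field(default_factory=list)
    sweep_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.stimulus = np.asarray(self.stimulus, dtype=np.float64)
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValidationError(f"signal_kind must be one of {SIGNAL_KINDS}")
        if len(self.stimulus) != len(self.samples):
            raise ValidationError(
                "stimulus and samples must be sample-for-sample aligned: "
                f"{len(self.stimulus)} != {len(self.samples)}"
            )
        dur = self.duration
        for label, t0, t1 in self.epochs:
            if t0 < 0 or not t0 < t1:
                raise ValidationError(f"bad epoch ({label!r}, {t0}, {t1})")
            if t1 > dur + 1e-9:
                raise ValidationError(
                    f"epoch {label!r} ends at {t1} s, beyond trace end {dur} s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt

    def epoch_span(self, label: str) -> Optional[tuple[float, float]]:
        """Return (t_start, t_end) of the first epoch with ``label``, or None."""
        for lab, t0, t1 in self.epochs:
            if lab == label:
                return (t0, t1)
        return None

    def epoch_spans(self, label: str) -> list[tuple[float, float]]:
        return [(t0, t1) for lab, t0, t1 in self.epochs if lab == label]


@dataclass
class CellRecord:
    """All sweeps recorded from one cell plus metadata links."""

    cell_id: str
    iv_sweeps: list[Sweep] = field(default_factory=list)
    vc_trace: Optional[Sweep] = None
    patient_id: str = ""
    axonal_class: str = "not_recovered"
    ground_truth: Optional[Any] = None  # SynthTruth for simulated cells

    def __post_init__(self) -> None:
        if self.axonal_class not in AXONAL_CLASSES:
            raise ValidationError(
                f"axonal_class {self.axonal_class!r} not in {AXONAL_CLASSES}"
            )
        if self.iv_sweeps:
            dts = {sw.dt for sw in self.iv_sweeps}
            if len(dts) > 1:
                raise ValidationError("IV sweeps must share a sampling interval")
            lengths = {sw.n_samples for sw in self.iv_sweeps}
            if len(lengths) > 1:
                raise ValidationError("IV sweeps must share a sample count")
            # ordered by injected step current
            steps = [step_current(sw) for sw in self.iv_sweeps]
            if any(b < a for a, b in zip(steps, steps[1:])):
                self.iv_sweeps = [
                    sw for _, sw in sorted(zip(steps, self.iv_sweeps), key=lambda p: p[0])
                ]


def step_current(sweep: Sweep) -> float:
    """Injected step amplitude (pA) of a current-clamp sweep, relative to
    its pre-step holding current (median of stimulus extremes vs baseline)."""
    stim = sweep.stimulus
    base = stim[0]
    dev = stim - base
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


@dataclass
class PatientMeta:
    patient_id: str
    age: float
    sex: str
    pathology: str
    cortical_area: str
    seizure_history: str
    dexamethasone: str
    levetiracetam: bool
    hemisphere: str
    lobe: str

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        for value, levels, name in [
            (self.sex, SEX_LEVELS, "sex"),
            (self.seizure_history, SEIZURE_HISTORY_LEVELS, "seizure_history"),
            (self.dexamethasone, DEXAMETHASONE_LEVELS, "dexamethasone"),
            (self.hemisphere, HEMISPHERE_LEVELS, "hemisphere"),
            (self.lobe, LOBE_LEVELS, "lobe"),
        ]:
            if value not in levels:
                raise ValidationError(f"{name}={value!r} not in {levels}")


# ---------------------------------------------------------------------------
# interchange HDF5
# ---------------------------------------------------------------------------

def _write_sweep_group(grp: h5py.Group, sweep: Sweep) -> None:
    grp.create_dataset("samples", data=sweep.samples)
    grp.create_dataset("stimulus", data=sweep.stimulus)
    grp.attrs["dt"] = sweep.dt
    grp.attrs["signal_kind"] = sweep.signal_kind
    grp.attrs["sweep_id"] = sweep.sweep_id
    grp.attrs["units"] = "mV" if sweep.signal_kind == "voltage" else "pA"
    if sweep.epochs:
        labels = np.array([e[0] for e in sweep.epochs], dtype=h5py.string_dtype())
        grp.create_dataset("epoch_labels", data=labels)
        grp.create_dataset(
            "epoch_times", data=np.array([[e[1], e[2]] for e in sweep.epochs])
        )


def _read_sweep_group(grp: h5py.Group) -> Sweep:
    if "dt" not in grp.attrs:
        raise FormatError(f"sweep group {grp.name!r} lacks dt metadata")
    if "signal_kind" not in grp.attrs or "units" not in grp.attrs:
        raise FormatError(f"sweep group {grp.name!r} lacks units metadata")
    epochs: list[tuple[str, float, float]] = []
    if "epoch_labels" in grp:
        labels = [l.decode() if isinstance(l, bytes) else str(l) for l in grp["epoch_labels"][()]]
        times = grp["epoch_times"][()]
        epochs = [(lab, float(t0), float(t1)) for lab, (t0, t1) in zip(labels, times)]
    return Sweep(
        samples=grp["samples"][()],
        stimulus=grp["stimulus"][()],
        dt=float(grp.attrs["dt"]),
        signal_kind=str(grp.attrs["signal_kind"]),
        epochs=epochs,
        sweep_id=str(grp.attrs.get("sweep_id", "")),
    )


def write_cell(record: CellRecord, path: str | Path, format: str = "interchange-h5") -> Path:
    """Write a :class:`CellRecord` to ``path`` in the requested layout."""
    path = Path(path)
    if format == "interchange-h5":
        with h5py.File(path, "w") as f:
            f.attrs["cell_id"] = record.cell_id
            f.attrs["patient_id"] = record.patient_id
            f.attrs["axonal_class"] = record.axonal_class
            iv = f.create_group("iv_sweeps")
            for i, sw in enumerate(record.iv_sweeps):
                _write_sweep_group(iv.create_group(f"sweep_{i:03d}"), sw)
            if record.vc_trace is not None:
                _write_sweep_group(f.create_group("vc_trace"), record.vc_trace)
            if record.ground_truth is not None:
                f.attrs["ground_truth_json"] = json.dumps(
                    _truth_to_dict(record.ground_truth)
                )
        return path
    if format == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        meta: dict[str, Any] = {
            "cell_id": record.cell_id,
            "patient_id": record.patient_id,
            "axonal_class": record.axonal_class,
            "iv_sweeps": [],
        }
        for i, sw in enumerate(record.iv_sweeps):
            name = f"iv_{i:03d}"
            _write_sweep_csv(path, name, sw)
            meta["iv_sweeps"].append(_sweep_sidecar(name, sw))
        if record.vc_trace is not None:
            _write_sweep_csv(path, "vc", record.vc_trace)
            meta["vc_trace"] = _sweep_sidecar("vc", record.vc_trace)
        if record.ground_truth is not None:
            meta["ground_truth"] = _truth_to_dict(record.ground_truth)
        (path / "cell.json").write_text(json.dumps(meta, indent=1))
        return path
    raise ValueError(f"unknown format {format!r}")


def _write_sweep_csv(dirpath: Path, name: str, sweep: Sweep) -> None:
    t = sweep.time
    for fname, values in [(f"{name}.csv", sweep.samples), (f"{name}.stim.csv", sweep.stimulus)]:
        with open(dirpath / fname, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t_s", "value"])
            for ti, vi in zip(t, values):
                w.writerow([repr(float(ti)), repr(float(vi))])


def _sweep_sidecar(name: str, sweep: Sweep) -> dict:
    return {
        "name": name,
        "dt": sweep.dt,
        "signal_kind": sweep.signal_kind,
        "units": "mV" if sweep.signal_kind == "voltage" else "pA",
        "sweep_id": sweep.sweep_id,
        "epochs": [list(e) for e in sweep.epochs],
    }


def _read_sweep_csv(dirpath: Path, sidecar: dict) -> Sweep:
    if "dt" not in sidecar:
        raise FormatError(f"sidecar for {sidecar.get('name')} lacks dt metadata")
    if "units" not in sidecar or "signal_kind" not in sidecar:
        raise FormatError(f"sidecar for {sidecar.get('name')} lacks units metadata")
    name = sidecar["name"]

    def _load(fname: str) -> np.ndarray:
        with open(dirpath / fname, newline="") as fh:
            r = csv.reader(fh)
            header = next(r)
            if header[:2] != ["t_s", "value"]:
                raise FormatError(f"{fname}: expected header t_s,value")
            return np.array([float(row[1]) for row in r])

    return Sweep(
        samples=_load(f"{name}.csv"),
        stimulus=_load(f"{name}.stim.csv"),
        dt=float(sidecar["dt"]),
        signal_kind=sidecar["signal_kind"],
        epochs=[(e[0], float(e[1]), float(e[2])) for e in sidecar.get("epochs", [])],
        sweep_id=sidecar.get("sweep_id", ""),
    )


def read_cell(path: str | Path, format: str = "interchange-h5") -> CellRecord:
    """Read a :class:`CellRecord` written by :func:`write_cell`.

    ``format`` is one of ``interchange-h5``, ``csv-dir`` or ``nwb``
    (the latter requires :mod:`pynwb`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "interchange-h5":
        with h5py.File(path, "r") as f:
            iv = [
                _read_sweep_group(f["iv_sweeps"][k])
                for k in sorted(f["iv_sweeps"].keys())
            ]
            vc = _read_sweep_group(f["vc_trace"]) if "vc_trace" in f else None
            truth = None
            if "ground_truth_json" in f.attrs:
                truth = _truth_from_dict(json.loads(f.attrs["ground_truth_json"]))
            rec = CellRecord(
                cell_id=str(f.attrs["cell_id"]),
                iv_sweeps=iv,
                vc_trace=vc,
                patient_id=str(f.attrs.get("patient_id", "")),
                axonal_class=str(f.attrs.get("axonal_class", "not_recovered")),
                ground_truth=truth,
            )
        _check_iv_lengths(rec)
        return rec
    if format == "csv-dir":
        meta = json.loads((path / "cell.json").read_text())
        iv = [_read_sweep_csv(path, sc) for sc in meta.get("iv_sweeps", [])]
        vc = _read_sweep_csv(path, meta["vc_trace"]) if "vc_trace" in meta else None
        truth = _truth_from_dict(meta["ground_truth"]) if "ground_truth" in meta else None
        rec = CellRecord(
            cell_id=meta["cell_id"],
            iv_sweeps=iv,
            vc_trace=vc,
            patient_id=meta.get("patient_id", ""),
            axonal_class=meta.get("axonal_class", "not_recovered"),
            ground_truth=truth,
        )
        _check_iv_lengths(rec)
        return rec
    if format == "nwb":
        return _read_nwb(path)
    raise ValueError(f"unknown format {format!r}")


def _check_iv_lengths(rec: CellRecord) -> None:
    lengths = {sw.n_samples for sw in rec.iv_sweeps}
    if len(lengths) > 1:
        raise ValidationError(
            f"mixed sweep lengths within IV protocol of cell {rec.cell_id}: {sorted(lengths)}"
        )


def _read_nwb(path: Path) -> CellRecord:  # pragma: no cover - optional reader
    try:
        import pynwb  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "reading NWB files requires the optional pynwb dependency"
        ) from exc
    from pynwb import NWBHDF5IO

    iv: list[Sweep] = []
    with NWBHDF5IO(str(path), "r") as io:
        nwb = io.read()
        for name, ts in nwb.acquisition.items():
            rate = getattr(ts, "rate", None)
            if rate is None:
                raise FormatError(f"NWB series {name} lacks a sampling rate")
            data = np.asarray(ts.data[:], dtype=float)
            unit = (ts.unit or "").lower()
            if unit in ("volt", "volts", "v"):
                data = data * 1e3
                kind = "voltage"
            elif unit in ("ampere", "amperes", "amp", "a"):
                data = data * 1e12
                kind = "current"
            else:
                raise FormatError(f"NWB series {name} has unknown unit {ts.unit!r}")
            iv.append(
                Sweep(
                    samples=data,
                    stimulus=np.zeros_like(data),
                    dt=1.0 / float(rate),
                    signal_kind=kind,
                    sweep_id=name,
                )
            )
    return CellRecord(cell_id=path.stem, iv_sweeps=iv)


# ---------------------------------------------------------------------------
# ground-truth serialization hooks (SynthTruth lives in synthetic_data)
# ---------------------------------------------------------------------------

def _truth_to_dict(truth: Any) -> dict:
    if hasattr(truth, "to_dict"):
        return truth.to_dict()
    if isinstance(truth, dict):
        return truth
    raise TypeError(f"cannot serialize ground truth of type {type(truth)}")


def _truth_from_dict(d: dict) -> Any:
    from .synthetic_data import SynthTruth

    return SynthTruth.from_dict(d)


# ---------------------------------------------------------------------------
# patient table
# ---------------------------------------------------------------------------

def read_patient_table(path: str | Path) -> list[PatientMeta]:
    """Parse the fixed-header patient covariate CSV.

    Enumerated columns use closed vocabularies (see module constants);
    unknown categories and duplicated patient ids are rejected.
    """
    path = Path(path)
    out: list[PatientMeta] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != PATIENT_TABLE_HEADER:
            raise FormatError(
                f"patient table must have header {','.join(PATIENT_TABLE_HEADER)}"
            )
        for row in reader:
            pid = row["patient_id"].strip()
            if pid in seen:
                raise ValidationError(f"duplicated patient_id {pid!r}")
            seen.add(pid)
            lev = row["levetiracetam"].strip().lower()
            if lev not in ("true", "false", "1", "0", "yes", "no"):
                raise ValidationError(f"levetiracetam={row['levetiracetam']!r} not boolean")
            out.append(
                PatientMeta(
                    patient_id=pid,
                    age=float(row["age"]),
                    sex=row["sex"].strip(),
                    pathology=row["pathology"].strip(),
                    cortical_area=row["cortical_area"].strip(),
                    seizure_history=row["seizure_history"].strip(),
                    dexamethasone=row["dexamethasone"].strip(),
                    levetiracetam=lev in ("true", "1", "yes"),
                    hemisphere=row["hemisphere"].strip(),
                    lobe=row["lobe"].strip(),
                )
            )
    return out


def write_patient_table(patients: Sequence[PatientMeta], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_TABLE_HEADER)
        for p in patients:
            w.writerow(
                [
                    p.patient_id,
                    repr(float(p.age)),
                    p.sex,
                    p.pathology,
                    p.cortical_area,
                    p.seizure_history,
                    p.dexamethasone,
                    str(p.levetiracetam).lower(),
                    p.hemisphere,
                    p.lobe,
                ]
            )
    return path
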