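"""EEG input/output for the 19-lead 10-20 dry-electrode montage.

Defines the fixed montage used throughout the package, the partition of the
scalp into four cortical regions (frontal, central, parietal, occipital),
and readers/writers for the two supported on-disk formats:

* a diff-friendly CSV dialect (first column = lead label, remaining columns
  = samples in microvolts, sampling rate on a ``# fs=<Hz>`` metadata line);
* EDF (European Data Format), read through :mod:`mne` and written with a
  minimal single-record-per-second 16-bit writer.

The four region lead lists are an exhaustive partition of the standard
19-lead set.  The source protocol gives only range endpoints ("Fp1 to F8",
"Cz to T4", "Pz to P4", "P7 to O2") plus the frontal count of 7; literal
contiguous 10-20 ranges for all four would overlap, so the partition below
is the unique consistent reading given the frontal count (see
``docs/methods.md``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "LEADS_1020",
    "REGION_LEADS",
    "LEAD_SYNONYMS",
    "Montage",
    "EEGRecording",
    "standard_montage",
    "region_leads",
    "read_eeg",
    "write_eeg",
]

#: Canonical lead order of the 19-channel 10-20 montage.
LEADS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Modern 10-10 style names accepted as synonyms of the classic 10-20 names.
LEAD_SYNONYMS: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

#: Cortical regions: a partition of the 19 leads (7 + 5 + 3 + 4).
REGION_LEADS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
    "central": ("T3", "C3", "Cz", "C4", "T4"),
    "parietal": ("P3", "Pz", "P4"),
    "occipital": ("T5", "T6", "O1", "O2"),
}


def _canonical_label(raw: str) -> str | None:
    """Map a raw channel label onto a canonical montage lead, or None."""
    s = raw.strip()
    # strip common EDF prefixes/suffixes such as "EEG Fp1-REF"
    for prefix in ("EEG ", "eeg "):
        if s.startswith(prefix):
            s = s[len(prefix):]
    s = s.split("-")[0].strip()
    lower = {name.lower(): name for name in LEADS_1020}
    lower.update({syn.lower(): tgt for syn, tgt in LEAD_SYNONYMS.items()})
    return lower.get(s.lower())


@dataclass(frozen=True)
class Montage:
    """Ordered 19-lead montage with a lead -> region map."""

    leads: tuple[str, ...] = LEADS_1020
    region_map: Mapping[str, str] = field(
        default_factory=lambda: {
            lead: region for region, leads in REGION_LEADS.items() for lead in leads
        }
    )

    def __post_init__(self) -> None:
        if len(self.leads) != 19:
            raise ValueError(f"montage must have exactly 19 leads, got {len(self.leads)}")
        if len(set(self.leads)) != 19:
            raise ValueError("montage lead names must be unique")
        if set(self.region_map) != set(self.leads):
            raise ValueError("region_map must cover exactly the montage leads")
        n_frontal = sum(1 for r in self.region_map.values() if r == "frontal")
        if n_frontal != 7:
            raise ValueError(f"frontal region must have 7 leads, got {n_frontal}")

    def index(self, lead: str) -> int:
        return self.leads.index(lead)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(REGION_LEADS)


def standard_montage() -> Montage:
    """The package's fixed 19-lead montage."""
    return Montage()


def region_leads(montage: Montage, region: str) -> tuple[str, ...]:
    """Ordered leads belonging to *region* (frontal/central/parietal/occipital)."""
    if region not in REGION_LEADS:
        raise ValueError(
            f"unknown region {region!r}; expected one of {sorted(REGION_LEADS)}"
        )
    return tuple(l for l in montage.leads if montage.region_map[l] == region)


@dataclass
class EEGRecording:
    """One subject-week of resting EEG: lead x sample matrix in microvolts."""

    data: np.ndarray
    fs: float
    montage: Montage = field(default_factory=standard_montage)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 19:
            raise ValueError(f"data must be 19 x n_samples, got shape {self.data.shape}")
        if self.fs < 40:
            raise ValueError(f"sampling rate {self.fs} Hz too low; need >= 40 Hz "
                             "to resolve the 2-20 Hz band")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.data[self.montage.index(name)]


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _read_csv(path: Path, montage: Montage) -> EEGRecording:
    fs = None
    rows: dict[str, np.ndarray] = {}
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta = line.lstrip("#").strip()
                if meta.startswith("fs="):
                    fs = float(meta.split("=", 1)[1])
                continue
            label, _, rest = line.partition(",")
            canon = _canonical_label(label)
            if canon is None:
                raise ValueError(f"{path}: unrecognized lead label {label!r}")
            rows[canon] = np.array(rest.split(","), dtype=float)
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' metadata line")
    missing = [l for l in montage.leads if l not in rows]
    if missing:
        raise ValueError(f"{path}: missing leads {missing}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: leads have unequal sample counts {sorted(lengths)}")
    data = np.vstack([rows[l] for l in montage.leads])
    return EEGRecording(data=data, fs=fs, montage=montage)


def _write_csv(rec: EEGRecording, path: Path, fmt: str = "%.8g") -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        for i, lead in enumerate(rec.montage.leads):
            buf = io.StringIO()
            np.savetxt(buf, rec.data[i][None, :], fmt=fmt, delimiter=",")
            fh.write(f"{lead},{buf.getvalue().strip()}\n")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf(path: Path, montage: Montage) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = {}
    for idx, ch in enumerate(raw.ch_names):
        canon = _canonical_label(ch)
        if canon is not None and canon not in labels:
            labels[canon] = idx
    missing = [l for l in montage.leads if l not in labels]
    if missing:
        raise ValueError(f"{path}: EDF is missing montage leads {missing}")
    data_v = raw.get_data()  # volts
    data = np.vstack([data_v[labels[l]] for l in montage.leads]) * 1e6
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]), montage=montage)


def _ascii(value: object, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: 1-second records, 16-bit samples, unit uV.

    Requires an integer sampling rate and a whole number of seconds; pad or
    resample upstream if needed.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    n_records = rec.n_samples // fs_i
    if n_records * fs_i != rec.n_samples:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    ns = 19

    # Per-channel physical range; re-parse the ASCII header values so the
    # round trip uses exactly the scaling a reader will reconstruct.
    pmins, pmaxs = [], []
    for i in range(ns):
        amp = float(np.max(np.abs(rec.data[i])))
        amp = max(amp * 1.0001, 1.0)
        pmax_s = f"{amp:.6g}"[:8]
        pmaxs.append(float(pmax_s))
        pmins.append(-float(pmax_s))

    dmin, dmax = -32768, 32767
    header = b"".join([
        _ascii(0, 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X X X X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (ns + 1), 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),
        _ascii(ns, 4),
    ])
    fields: list[bytes] = []
    fields += [_ascii(l, 16) for l in rec.montage.leads]
    fields += [_ascii("", 80)] * ns
    fields += [_ascii("uV", 8)] * ns
    fields += [_ascii(f"{p:.6g}"[:8], 8) for p in pmins]
    fields += [_ascii(f"{p:.6g}"[:8], 8) for p in pmaxs]
    fields += [_ascii(dmin, 8)] * ns
    fields += [_ascii(dmax, 8)] * ns
    fields += [_ascii("", 80)] * ns
    fields += [_ascii(fs_i, 8)] * ns
    fields += [_ascii("", 32)] * ns

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        for rec_i in range(n_records):
            sl = slice(rec_i * fs_i, (rec_i + 1) * fs_i)
            for ch in range(ns):
                x = rec.data[ch, sl]
                scale = (dmax - dmin) / (pmaxs[ch] - pmins[ch])
                dig = np.rint((x - pmins[ch]) * scale + dmin)
                dig = np.clip(dig, dmin, dmax).astype("<i2")
                fh.write(dig.tobytes())


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format.lower()
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer EEG format from suffix {suffix!r}; pass format=")


def read_eeg(path: str | Path, format: str | None = None,
             montage: Montage | None = None) -> EEGRecording:
    """Read an EEG recording (CSV or EDF) with rows ordered per the montage.

    Lead labels are matched case-insensitively; the T3/T7, T4/T8, T5/P7,
    T6/P8 synonym pairs are accepted.  A file missing any montage lead is a
    hard error naming the absent labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    montage = montage or standard_montage()
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path, montage)
    if fmt == "edf":
        return _read_edf(path, montage)
    raise ValueError(f"unsupported EEG format {fmt!r}")


def write_eeg(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    """Write *rec* as CSV (full float precision) or EDF (16-bit quantized)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unsupported EEG format {fmt!r}")
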