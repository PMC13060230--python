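"""Session data model, on-disk format, and stream alignment.

A *session* is one simultaneous recording of two-channel fiber photometry
(calcium-dependent signal plus isosbestic reference) and arterial glucose,
both sampled at 1 Hz on a common time axis anchored so that ``t = 0`` is the
oral-gavage (or sham) event.  Sessions are stored as a plain CSV table with
columns ``time_s, fp_signal, fp_reference, glucose`` next to a JSON metadata
sidecar, so raw streams stay inspectable with standard tools.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("photoglu")

#: Required CSV columns, in on-disk order.
CSV_COLUMNS = ("time_s", "fp_signal", "fp_reference", "glucose")

#: Minimum overlap (seconds) the two acquisition streams must share around
#: the event: 25 min of baseline + 90 min of follow-up.
MIN_OVERLAP_S = 115 * 60

#: Gaps up to this many seconds are bridged by linear interpolation at load
#: time; anything longer invalidates the session.
MAX_GAP_S = 5


class SessionError(ValueError):
    """Malformed session file or violated session invariant."""


class AlignmentError(SessionError):
    """Photometry and glucose streams do not overlap long enough."""


@dataclass
class Session:
    """One recording: paired photometry and glucose on a 1 Hz event-anchored grid.

    Parameters
    ----------
    subject_id : str
        Animal identifier.
    dose : float
        Oral glucose dose in g per kg body weight (0 for water).
    t : ndarray
        Time in seconds relative to the gavage event; strictly increasing
        with constant 1 s spacing.
    fp_signal, fp_reference : ndarray
        Calcium-dependent and isosbestic fluorescence (arbitrary units).
    glucose : ndarray
        Arterial glucose, mg/dL.
    session_order : int
        Ordinal exposure number for the animal (1 = first gavage); used by
        learned-anticipation analyses.
    ground_truth : dict or None
        For synthetic sessions only: named component traces (anticipatory,
        second-phase, true glucose derivative, ...) kept for recovery tests.
    """

    subject_id: str
    dose: float
    t: np.ndarray
    fp_signal: np.ndarray
    fp_reference: np.ndarray
    glucose: np.ndarray
    session_order: int = 1
    notes: str = ""
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fp_signal = np.asarray(self.fp_signal, dtype=float)
        self.fp_reference = np.asarray(self.fp_reference, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n = self.t.size
        for name in ("fp_signal", "fp_reference", "glucose"):
            arr = getattr(self, name)
            if arr.size != n:
                raise SessionError(
                    f"column {name!r} has length {arr.size}, expected {n}"
                )
        if n < 2:
            raise SessionError("session must contain at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise SessionError(
                f"time axis not strictly increasing at row {i + 1} "
                f"(time_s={self.t[i + 1]!r})"
            )
        if not np.allclose(dt, 1.0, atol=1e-6):
            i = int(np.argmax(np.abs(dt - 1.0) > 1e-6))
            raise SessionError(
                f"non-uniform sampling at row {i + 1}: spacing {dt[i]:g} s "
                "(expected 1 s)"
            )
        if self.dose < 0:
            raise SessionError(f"dose must be non-negative, got {self.dose}")

    @property
    def n(self) -> int:
        return self.t.size

    def copy(self) -> "Session":
        gt = None if self.ground_truth is None else dict(self.ground_truth)
        return replace(
            self,
            t=self.t.copy(),
            fp_signal=self.fp_signal.copy(),
            fp_reference=self.fp_reference.copy(),
            glucose=self.glucose.copy(),
            ground_truth=gt,
        )

    def time_mask(self, window_min: tuple[float, float], closed: str = "left") -> np.ndarray:
        """Boolean mask for ``t`` inside ``window_min`` (minutes).

        ``closed='left'`` gives the half-open interval [lo, hi) used for the
        pre-event baseline so the event sample itself is excluded;
        ``closed='both'`` includes both endpoints.
        """
        lo, hi = (60.0 * w for w in window_min)
        if lo < self.t[0] - 1e-9 or hi > self.t[-1] + 1e-9:
            raise SessionError(
                f"window [{window_min[0]}, {window_min[1]}] min outside session "
                f"support [{self.t[0] / 60:g}, {self.t[-1] / 60:g}] min"
            )
        if closed == "left":
            return (self.t >= lo - 1e-9) & (self.t < hi - 1e-9)
        return (self.t >= lo - 1e-9) & (self.t <= hi + 1e-9)


# -- on-disk format ---------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _truth_path(path: Path) -> Path:
    return path.with_name(path.stem + "_truth.csv")


def _fill_short_gaps(t: np.ndarray, values: np.ndarray, column: str) -> np.ndarray:
    """Interpolate NaN runs of <= MAX_GAP_S samples; longer gaps are fatal."""
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    # length of each NaN run
    idx = np.flatnonzero(bad)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    longest = max(len(run) for run in splits)
    if longest > MAX_GAP_S:
        raise SessionError(
            f"column {column!r} has a {longest} s gap (limit {MAX_GAP_S} s)"
        )
    if bad[0] or bad[-1]:
        raise SessionError(f"column {column!r} has missing samples at the trace edge")
    logger.warning(
        "column %r: interpolating %d missing samples (%d gap(s))",
        column, int(bad.sum()), len(splits),
    )
    out = values.copy()
    out[bad] = np.interp(t[bad], t[~bad], values[~bad])
    return out


def load_session(path: str | Path) -> Session:
    """Read one session from ``path`` (CSV) and its JSON metadata sidecar.

    Missing samples are flagged: gaps of at most 5 s are linearly
    interpolated with a logged warning, longer gaps raise
    :class:`SessionError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SessionError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise SessionError(f"{path}: missing column(s) {missing}")

    t = table["time_s"].to_numpy(dtype=float)
    if t.size > 1:
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            raise SessionError(
                f"{path}: duplicated timestamp {t[dup[0]]:g} at row {dup[0] + 2}"
            )

    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
        except json.JSONDecodeError as exc:
            raise SessionError(f"cannot parse metadata sidecar {sidecar}: {exc}") from exc

    columns = {}
    for name in ("fp_signal", "fp_reference", "glucose"):
        columns[name] = _fill_short_gaps(t, table[name].to_numpy(dtype=float), name)

    truth = None
    tp = _truth_path(path)
    if tp.exists():
        truth_table = pd.read_csv(tp)
        truth = {c: truth_table[c].to_numpy(dtype=float) for c in truth_table.columns}

    return Session(
        subject_id=str(meta.get("subject_id", path.stem)),
        dose=float(meta.get("dose_g_per_kg", 0.0)),
        t=t,
        session_order=int(meta.get("session_order", 1)),
        notes=str(meta.get("notes", "")),
        ground_truth=truth,
        **columns,
    )


def save_session(session: Session, path: str | Path) -> Path:
    """Write ``session`` as CSV + JSON sidecar; round-trips through
    :func:`load_session` bit-for-bit up to float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {
            "time_s": session.t,
            "fp_signal": session.fp_signal,
            "fp_reference": session.fp_reference,
            "glucose": session.glucose,
        }
    )
    table.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "subject_id": session.subject_id,
        "dose_g_per_kg": session.dose,
        "event_time_s": 0.0,
        "session_order": session.session_order,
        "notes": session.notes,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    if session.ground_truth is not None:
        scalars = {k: v for k, v in session.ground_truth.items() if np.ndim(v) == 0}
        arrays = {k: v for k, v in session.ground_truth.items() if np.ndim(v) != 0}
        frame = pd.DataFrame(arrays)
        for k, v in scalars.items():  # broadcast scalars into columns
            frame[k] = float(v)
        frame.to_csv(_truth_path(path), index=False, float_format="%.17g")
    return path


# -- stream alignment -------------------------------------------------------


def align_streams(
    fp_t: np.ndarray,
    fp: np.ndarray,
    glu_t: np.ndarray,
    glu: np.ndarray,
    event_time: float,
    *,
    subject_id: str = "unknown",
    dose: float = 0.0,
    session_order: int = 1,
) -> Session:
    """Resample photometry and glucose onto a shared event-anchored 1 Hz grid.

    ``fp`` has shape ``(2, n)`` with rows (signal, reference). Both streams
    are linearly interpolated onto integer seconds relative to
    ``event_time``; no extrapolation beyond either stream's support is
    performed. Raises :class:`AlignmentError` when the overlap around the
    event is shorter than 115 min.
    """
    fp_t = np.asarray(fp_t, dtype=float)
    glu_t = np.asarray(glu_t, dtype=float)
    fp = np.atleast_2d(np.asarray(fp, dtype=float))
    if fp.shape[0] != 2:
        raise SessionError(f"fp must have two channel rows, got shape {fp.shape}")

    start = max(fp_t[0], glu_t[0])
    stop = min(fp_t[-1], glu_t[-1])
    if stop - start < MIN_OVERLAP_S:
        raise AlignmentError(
            f"streams overlap for only {(stop - start) / 60:.1f} min "
            f"(need >= {MIN_OVERLAP_S / 60:.0f} min); "
            f"available span [{start:g}, {stop:g}] s"
        )
    t0 = np.ceil(start - event_time)
    t1 = np.floor(stop - event_time)
    t = np.arange(t0, t1 + 0.5)
    abs_t = t + event_time
    return Session(
        subject_id=subject_id,
        dose=dose,
        t=t,
        fp_signal=np.interp(abs_t, fp_t, fp[0]),
        fp_reference=np.interp(abs_t, fp_t, fp[1]),
        glucose=np.interp(abs_t, glu_t, glu),
        session_order=session_order,
    )


# -- cohort manifest --------------------------------------------------------


def load_manifest(path: str | Path) -> list[Session]:
    """Load every session listed in a manifest CSV.

    The manifest has a ``path`` column (relative paths resolved against the
    manifest's directory) plus optional per-row overrides of
    ``subject_id``, ``dose_g_per_kg`` and ``session_order``.
    """
    path = Path(path)
    table = pd.read_csv(path)
    if "path" not in table.columns:
        raise SessionError(f"{path}: manifest needs a 'path' column")
    sessions = []
    for _, row in table.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        s = load_session(p)
        if "subject_id" in row and not pd.isna(row.get("subject_id")):
            s.subject_id = str(row["subject_id"])
        if "dose_g_per_kg" in row and not pd.isna(row.get("dose_g_per_kg")):
            s.dose = float(row["dose_g_per_kg"])
        if "session_order" in row and not pd.isna(row.get("session_order")):
            s.session_order = int(row["session_order"])
        sessions.append(s)
    return sessions


def save_cohort(sessions: list[Session], out_dir: str | Path) -> Path:
    """Write every session plus a manifest CSV into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(sessions):
        name = f"{s.subject_id}_s{s.session_order:02d}.csv"
        save_session(s, out_dir / name)
        rows.append(
            {
                "path": name,
                "subject_id": s.subject_id,
                "dose_g_per_kg": s.dose,
                "session_order": s.session_order,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
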