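"""CSV dialects and in-memory containers for melt curves, MST traces and titrations.

All files are comma-separated, UTF-8, "." decimal, with a mandatory header row.
Temperatures are degrees Celsius on disk and Kelvin in memory; concentrations
are molar everywhere (scientific notation is fine on disk).  Unit conversion
happens only here, at the I/O boundary.

Dialects
--------
melt CSV            ``Temperature_C,<well_id_1>,<well_id_2>,...``
melt annotation     ``well_id,condition,ligand_conc_M,replicate``
MST trace CSV       ``capillary_id,time_s,fluorescence``  (long format)
MST annotation      ``capillary_id,ligand_conc_M,protein_conc_M``
titration CSV       ``ligand_conc_M,signal``
result CSV          ``fit_id,model,parameter,estimate,std_error,rel_error_pct,
                      ci95_low,ci95_high,flags``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

CELSIUS_OFFSET = 273.15

#: signals a melt experiment can report
CHANNELS = ("F330", "F350", "ratio_350_330", "scattering", "dye")

ANNOTATION_COLUMNS = ["condition", "ligand_conc_M", "replicate"]


class DialectError(ValueError):
    """Raised when a file does not conform to one of the documented dialects."""


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + CELSIUS_OFFSET


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - CELSIUS_OFFSET


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MeltCurveSet:
    """A set of melting traces on a common temperature grid.

    Parameters
    ----------
    temperature_K : (n_T,) strictly increasing grid in Kelvin (>=5 points).
    signals : (n_wells, n_T) fluorescence/scattering matrix, arbitrary units.
    well_ids : opaque well/capillary labels, one per signal row.
    annotations : per-well ``condition``, ``ligand_conc_M`` (molar, NaN if
        unknown) and ``replicate``, indexed by well id.
    channel : which optical signal the matrix holds.
    """

    temperature_K: np.ndarray
    signals: np.ndarray
    well_ids: list[str]
    annotations: pd.DataFrame = None
    channel: str = "dye"

    def __post_init__(self):
        self.temperature_K = np.asarray(self.temperature_K, dtype=float)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.well_ids = [str(w) for w in self.well_ids]
        if self.temperature_K.size < 5:
            raise DialectError("temperature grid needs at least 5 points")
        if np.any(np.diff(self.temperature_K) <= 0):
            bad = int(np.argmax(np.diff(self.temperature_K) <= 0)) + 1
            raise DialectError(f"temperature grid not strictly increasing at row {bad + 1}")
        if self.signals.shape != (len(self.well_ids), self.temperature_K.size):
            raise DialectError(
                f"signal matrix shape {self.signals.shape} does not match "
                f"{len(self.well_ids)} wells x {self.temperature_K.size} temperatures"
            )
        if len(set(self.well_ids)) != len(self.well_ids):
            raise DialectError("duplicate well_id")
        if self.channel not in CHANNELS:
            raise DialectError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.annotations is None:
            self.annotations = _empty_annotations(self.well_ids)
        else:
            self.annotations = self.annotations.reindex(self.well_ids)
            lig = self.annotations["ligand_conc_M"].to_numpy(dtype=float)
            if np.any(lig[np.isfinite(lig)] < 0):
                raise DialectError("ligand concentrations must be >= 0")

    @property
    def n_wells(self) -> int:
        return len(self.well_ids)

    def trace(self, well_id: str) -> np.ndarray:
        return self.signals[self.well_ids.index(well_id)]

    def ligand_conc(self, well_id: str) -> float:
        return float(self.annotations.loc[well_id, "ligand_conc_M"])

    def select_wells(self, wells: Sequence[str]) -> "MeltCurveSet":
        idx = [self.well_ids.index(w) for w in wells]
        return MeltCurveSet(
            self.temperature_K.copy(),
            self.signals[idx].copy(),
            [self.well_ids[i] for i in idx],
            self.annotations.loc[list(wells)].copy(),
            self.channel,
        )


def _empty_annotations(well_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {"condition": ["" for _ in well_ids],
         "ligand_conc_M": np.nan,
         "replicate": ["" for _ in well_ids]},
        index=pd.Index([str(w) for w in well_ids], name="well_id"),
    )


@dataclass
class MstTraceSet:
    """Per-capillary fluorescence-vs-time traces from an MST run.

    The time grid is shared by all capillaries and must span both sides of
    t = 0 s (IR-laser switch-on) so that cold and hot windows can be placed.
    Capillaries are ordered by descending ligand concentration.
    """

    time_s: np.ndarray
    fluorescence: np.ndarray
    capillary_ids: list[str]
    ligand_conc_M: np.ndarray
    protein_conc_M: float

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.atleast_2d(np.asarray(self.fluorescence, dtype=float))
        self.capillary_ids = [str(c) for c in self.capillary_ids]
        self.ligand_conc_M = np.asarray(self.ligand_conc_M, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise DialectError("time grid not strictly increasing")
        if not (self.time_s[0] < 0 < self.time_s[-1]):
            raise DialectError("time grid must span negative (pre-IR) and positive times")
        if self.fluorescence.shape != (len(self.capillary_ids), self.time_s.size):
            raise DialectError("fluorescence matrix shape mismatch")
        if np.any(self.ligand_conc_M < 0) or self.protein_conc_M <= 0:
            raise DialectError("concentrations must be non-negative (protein > 0)")
        # canonical order: descending ligand concentration
        order = np.argsort(-self.ligand_conc_M, kind="stable")
        self.ligand_conc_M = self.ligand_conc_M[order]
        self.fluorescence = self.fluorescence[order]
        self.capillary_ids = [self.capillary_ids[i] for i in order]

    @property
    def n_capillaries(self) -> int:
        return len(self.capillary_ids)


@dataclass
class TitrationTable:
    """Signal versus total ligand concentration, sorted ascending.

    ``response`` may be Fnorm, raw fluorescence or an unfolded fraction.
    Duplicate concentrations are technical replicates and are kept.
    """

    ligand_conc_M: np.ndarray
    response: np.ndarray
    replicate: list[str] = None

    def __post_init__(self):
        self.ligand_conc_M = np.asarray(self.ligand_conc_M, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.ligand_conc_M.shape != self.response.shape:
            raise DialectError("concentration/response length mismatch")
        if np.any(self.ligand_conc_M < 0):
            raise DialectError("ligand concentrations must be >= 0")
        if self.replicate is None:
            self.replicate = ["" for _ in self.ligand_conc_M]
        order = np.argsort(self.ligand_conc_M, kind="stable")
        self.ligand_conc_M = self.ligand_conc_M[order]
        self.response = self.response[order]
        self.replicate = [self.replicate[i] for i in order]

    @property
    def n_distinct(self) -> int:
        return np.unique(self.ligand_conc_M).size

    def require_fit_ready(self, minimum: int = 4) -> None:
        if self.n_distinct < minimum:
            raise DialectError(
                f"need >= {minimum} distinct ligand concentrations for a binding fit, "
                f"got {self.n_distinct}"
            )


RESULT_COLUMNS = [
    "fit_id", "model", "parameter", "estimate", "std_error",
    "rel_error_pct", "ci95_low", "ci95_high", "flags",
]


@dataclass
class ResultTable:
    """Long-format table of fitted parameters, one row per (fit, parameter)."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULT_COLUMNS))

    def __post_init__(self):
        missing = [c for c in RESULT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DialectError(f"result table missing columns {missing}")
        self.frame = (
            self.frame[RESULT_COLUMNS]
            .sort_values(["fit_id", "parameter"], kind="stable")
            .reset_index(drop=True)
        )

    @classmethod
    def from_fits(cls, fits) -> "ResultTable":
        """Build from an iterable of ``(fit_id, ModelFit)`` pairs."""
        rows = []
        for fit_id, fit in fits:
            rows.extend(fit.result_rows(fit_id))
        return cls(pd.DataFrame(rows, columns=RESULT_COLUMNS))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise DialectError(f"{path}: cannot parse CSV ({exc})") from exc


def _to_float(frame: pd.DataFrame, path) -> pd.DataFrame:
    out = frame.apply(pd.to_numeric, errors="coerce")
    if out.isna().to_numpy().any() and not frame.isna().to_numpy().any():
        r, c = np.argwhere(out.isna().to_numpy() & ~frame.isna().to_numpy())[0]
        raise DialectError(
            f"{path}: non-numeric cell at data row {r + 1}, column {frame.columns[c]!r}"
        )
    if out.isna().to_numpy().any():
        r, c = np.argwhere(out.isna().to_numpy())[0]
        raise DialectError(f"{path}: empty/non-numeric cell at data row {r + 1}, "
                           f"column {frame.columns[c]!r}")
    return out


def read_annotations(path) -> pd.DataFrame:
    """Read a well/capillary annotation table (``well_id,condition,ligand_conc_M,replicate``)."""
    raw = _read_csv(path)
    if "well_id" not in raw.columns:
        raise DialectError(f"{path}: annotation file must have a 'well_id' column")
    ann = raw.set_index("well_id")
    if ann.index.duplicated().any():
        dup = ann.index[ann.index.duplicated()][0]
        raise DialectError(f"{path}: duplicate well_id {dup!r} in annotations")
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            ann[col] = "" if col != "ligand_conc_M" else np.nan
    ann["ligand_conc_M"] = pd.to_numeric(ann["ligand_conc_M"], errors="coerce")
    ann["condition"] = ann["condition"].fillna("")
    ann["replicate"] = ann["replicate"].fillna("")
    return ann[ANNOTATION_COLUMNS]


def read_melt_csv(path, annotation_path=None, channel: str = "dye") -> MeltCurveSet:
    """Read a wide melt-curve CSV (``Temperature_C`` + one column per well).

    Temperatures are converted to Kelvin.  If ``annotation_path`` is given,
    wells are joined to their condition/ligand annotations by well id;
    unannotated wells are kept with an empty annotation.
    """
    # peek at the raw header: pandas would silently rename duplicate columns
    import csv
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    if not header or header[0] != "Temperature_C":
        got = header[0] if header else None
        raise DialectError(f"{path}: first column must be 'Temperature_C', got {got!r}")
    if len(header) < 2:
        raise DialectError(f"{path}: no well columns")
    if len(set(header[1:])) != len(header[1:]):
        dup = next(w for w in header[1:] if header[1:].count(w) > 1)
        raise DialectError(f"{path}: duplicate well_id {dup!r}")
    raw = _read_csv(path)
    well_ids = [str(c) for c in raw.columns[1:]]
    num = _to_float(raw, path)
    t_c = num["Temperature_C"].to_numpy()
    bad = np.nonzero(np.diff(t_c) <= 0)[0]
    if bad.size:
        raise DialectError(
            f"{path}: temperature not strictly increasing at data row {bad[0] + 2} "
            f"(T = {t_c[bad[0] + 1]:g} after {t_c[bad[0]]:g})"
        )
    ann = read_annotations(annotation_path) if annotation_path is not None else None
    if ann is not None:
        ann = ann.reindex(well_ids)
        ann["condition"] = ann["condition"].fillna("")
        ann["replicate"] = ann["replicate"].fillna("")
        ann.index.name = "well_id"
    signals = num[raw.columns[1:]].to_numpy().T
    return MeltCurveSet(celsius_to_kelvin(t_c), signals, well_ids, ann, channel)


def read_mst_csv(path, annotation_path) -> MstTraceSet:
    """Read long-format MST traces plus their capillary annotation table.

    Every capillary in the trace file must be annotated with a ligand
    concentration; all capillaries must share one time grid.
    """
    raw = _read_csv(path)
    for col in ("capillary_id", "time_s", "fluorescence"):
        if col not in raw.columns:
            raise DialectError(f"{path}: missing column {col!r}")
    raw["time_s"] = pd.to_numeric(raw["time_s"], errors="raise")
    raw["fluorescence"] = pd.to_numeric(raw["fluorescence"], errors="raise")

    ann_raw = _read_csv(annotation_path)
    for col in ("capillary_id", "ligand_conc_M", "protein_conc_M"):
        if col not in ann_raw.columns:
            raise DialectError(f"{annotation_path}: missing column {col!r}")
    ann = ann_raw.set_index("capillary_id")
    ann["ligand_conc_M"] = pd.to_numeric(ann["ligand_conc_M"], errors="raise")
    ann["protein_conc_M"] = pd.to_numeric(ann["protein_conc_M"], errors="raise")

    cap_ids = list(dict.fromkeys(raw["capillary_id"]))  # keep file order
    grids, traces, ligs = [], [], []
    for cap in cap_ids:
        if cap not in ann.index:
            raise DialectError(f"{path}: capillary {cap!r} missing from annotations")
        sub = raw[raw["capillary_id"] == cap]
        grids.append(sub["time_s"].to_numpy())
        traces.append(sub["fluorescence"].to_numpy())
        ligs.append(float(ann.loc[cap, "ligand_conc_M"]))
    t0 = grids[0]
    for cap, g in zip(cap_ids, grids):
        if g.shape != t0.shape or not np.allclose(g, t0, rtol=0, atol=1e-12):
            raise DialectError(f"{path}: capillary {cap!r} has a ragged/mismatched time grid")
    fl = np.vstack(traces)
    if np.any(fl < 0):
        warnings.warn(f"{path}: negative fluorescence values present; keeping them",
                      stacklevel=2)
    ptot = float(ann["protein_conc_M"].iloc[0])
    return MstTraceSet(t0, fl, cap_ids, np.array(ligs), ptot)


def read_titration_csv(path) -> TitrationTable:
    """Read a two-column titration file (``ligand_conc_M,signal``), sorted ascending."""
    raw = _read_csv(path)
    for col in ("ligand_conc_M", "signal"):
        if col not in raw.columns:
            raise DialectError(f"{path}: missing column {col!r}")
    num = _to_float(raw[["ligand_conc_M", "signal"]], path)
    table = TitrationTable(num["ligand_conc_M"].to_numpy(), num["signal"].to_numpy())
    table.require_fit_ready()
    return table


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_melt_csv(mcs: MeltCurveSet, path, annotation_path=None) -> None:
    frame = pd.DataFrame({"Temperature_C": kelvin_to_celsius(mcs.temperature_K)})
    for i, well in enumerate(mcs.well_ids):
        frame[well] = mcs.signals[i]
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if annotation_path is not None:
        write_annotations(mcs.annotations, annotation_path)


def write_annotations(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out.index.name = "well_id"
    out.to_csv(path, float_format=_FLOAT_FMT)


def write_mst_csv(traces: MstTraceSet, path, annotation_path=None) -> None:
    rows = {
        "capillary_id": np.repeat(traces.capillary_ids, traces.time_s.size),
        "time_s": np.tile(traces.time_s, traces.n_capillaries),
        "fluorescence": traces.fluorescence.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if annotation_path is not None:
        pd.DataFrame({
            "capillary_id": traces.capillary_ids,
            "ligand_conc_M": traces.ligand_conc_M,
            "protein_conc_M": traces.protein_conc_M,
        }).to_csv(annotation_path, index=False, float_format=_FLOAT_FMT)


def write_titration_csv(table: TitrationTable, path) -> None:
    pd.DataFrame({"ligand_conc_M": table.ligand_conc_M,
                  "signal": table.response}).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_result_table(table: ResultTable, path) -> None:
    """Write a result table with deterministic row/column order.

    Missing standard errors / CIs are rendered as empty fields.
    """
    table.frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_result_table(path) -> ResultTable:
    raw = pd.read_csv(path)
    for col in ("estimate", "std_error", "rel_error_pct", "ci95_low", "ci95_high"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce").astype(float)
    raw["flags"] = raw["flags"].fillna("")
    return ResultTable(raw)
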