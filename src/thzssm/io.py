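"""Reading and writing spectra and peak lists, and the packaged peak fixture.

Native exchange format is a two-column CSV (``freq_thz,absorbance``) with
``#``-prefixed comment lines carrying free-form metadata.  A minimal JCAMP-DX
subset (``##XYDATA=(X++(Y..Y))`` and ``##XYPOINTS=(XY..XY)``, AFFN numbers
only) is supported for interoperability with vibrational-spectroscopy tools.

The packaged fixture ``data/table1_peaks.tsv`` carries the fingerprint peak
inventory (DFT and experimental positions, strength labels, tabulated shifts,
vibrational-mode labels) of the eight fentanyl analogs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import DatabaseError, SpectrumParseError
from .types import DatabaseEntry, Peak, PeakList, SpectralDatabase, Spectrum

logger = logging.getLogger(__name__)

#: Convention mapping qualitative strength labels to relative amplitudes,
#: used both for fixture peak intensities and for synthetic line heights.
STRENGTH_AMPLITUDES = {"vw": 0.1, "w": 0.2, "m": 0.5, "s": 0.8, "vs": 1.0}

#: Analyte name abbreviations for the eight fentanyl analogs.
ANALOG_ABBREVIATIONS = {
    "fentanyl": "FN",
    "methoxyacetylfentanyl": "MF",
    "acetylfentanyl": "AF",
    "furanylfentanyl": "FF",
    "butyrylfentanyl": "BF",
    "4-fluoroisobutyrfentanyl": "FBF",
    "carfentanil": "CF",
    "valerylfentanyl": "VF",
}
ABBREVIATION_TO_NAME = {v: k for k, v in ANALOG_ABBREVIATIONS.items()}


# ---------------------------------------------------------------------------
# spectrum I/O
# ---------------------------------------------------------------------------

def read_spectrum(path, format: str | None = None, name: str | None = None) -> Spectrum:
    """Read a spectrum from ``path``.

    ``format`` is ``"csv"`` or ``"jcamp"``; when omitted it is inferred from
    the file suffix (``.jdx``/``.dx`` -> jcamp, anything else -> csv).  Rows
    are sorted by frequency and duplicate frequencies collapsed by mean.
    """
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in (".jdx", ".dx") else "csv"
    if format == "csv":
        freq, absorb, meta = _read_csv(path)
    elif format == "jcamp":
        freq, absorb, meta = _read_jcamp(path)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")
    freq, absorb = _sort_and_collapse(freq, absorb)
    label = name or meta.pop("name", None) or path.stem
    return Spectrum(label, freq, absorb, meta)


def _sort_and_collapse(freq, absorb):
    freq = np.asarray(freq, float)
    absorb = np.asarray(absorb, float)
    order = np.argsort(freq, kind="stable")
    freq, absorb = freq[order], absorb[order]
    uniq, inverse, counts = np.unique(freq, return_inverse=True, return_counts=True)
    if len(uniq) < len(freq):
        summed = np.zeros(len(uniq))
        np.add.at(summed, inverse, absorb)
        absorb = summed / counts
        freq = uniq
    return freq, absorb


def _read_csv(path: Path):
    meta: dict = {}
    freqs: list[float] = []
    absorbs: list[float] = []
    seen_data = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            cells = [c.strip() for c in line.split(",")]
            if len(cells) < 2:
                raise SpectrumParseError(
                    f"{path}: expected two comma-separated columns", line=lineno
                )
            try:
                f, a = float(cells[0]), float(cells[1])
            except ValueError:
                if not seen_data:
                    # a single optional header row is allowed
                    seen_data = True
                    continue
                raise SpectrumParseError(
                    f"{path}: non-numeric field {cells[0]!r}/{cells[1]!r}", line=lineno
                ) from None
            seen_data = True
            freqs.append(f)
            absorbs.append(a)
    return np.array(freqs), np.array(absorbs), meta


_JCAMP_XUNIT_TO_THZ = {"THZ": 1.0, "GHZ": 1e-3, "MHZ": 1e-6, "HZ": 1e-12}
# single letters used by SQZ/DIF/DUP compressed JCAMP forms we do not support
_JCAMP_COMPRESSED = set("@ABCDEFGHIabcdefghiJKLMNOPQRjklmnopqrSTUVWXYZs%")


def _jcamp_numbers(text: str, path, lineno: int) -> list[float]:
    toks = text.replace(",", " ").replace(";", " ").split()
    out = []
    for t in toks:
        try:
            out.append(float(t))
        except ValueError:
            if any(c in _JCAMP_COMPRESSED for c in t):
                raise SpectrumParseError(
                    f"{path}: compressed JCAMP data form (SQZ/DIF/DUP) is not supported",
                    line=lineno,
                ) from None
            raise SpectrumParseError(
                f"{path}: non-numeric JCAMP data token {t!r}", line=lineno
            ) from None
    return out


def _read_jcamp(path: Path):
    header: dict = {}
    meta: dict = {}
    mode = None  # None | "xydata" | "xypoints"
    raw: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.split("$$")[0].rstrip()
            if not line.strip():
                continue
            if line.startswith("##"):
                label, _, value = line[2:].partition("=")
                label = label.strip().upper().replace(" ", "")
                value = value.strip()
                if label == "XYDATA":
                    if "X++" not in value.replace(" ", ""):
                        raise SpectrumParseError(
                            f"{path}: unsupported XYDATA form {value!r}", line=lineno
                        )
                    mode = "xydata"
                elif label == "XYPOINTS":
                    mode = "xypoints"
                elif label == "END":
                    mode = None
                else:
                    if label.startswith("$META_"):
                        meta[label[len("$META_"):].lower()] = value
                    else:
                        header[label] = value
                    mode = None
                continue
            if mode is not None:
                raw.append((lineno, line))
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    xunits = header.get("XUNITS", "THZ").upper()
    if xunits not in _JCAMP_XUNIT_TO_THZ:
        raise SpectrumParseError(f"{path}: unsupported XUNITS {xunits!r}")
    xscale = _JCAMP_XUNIT_TO_THZ[xunits]

    if not raw:
        raise SpectrumParseError(f"{path}: no XYDATA/XYPOINTS block found")

    block_is_xydata = _scan_block_kind(path)
    if block_is_xydata:
        ys: list[float] = []
        for lineno, line in raw:
            nums = _jcamp_numbers(line, path, lineno)
            if not nums:
                continue
            ys.extend(nums[1:])  # first number on each line is the line's x
        if "FIRSTX" not in header or "LASTX" not in header:
            raise SpectrumParseError(f"{path}: XYDATA requires ##FIRSTX and ##LASTX")
        npoints = int(float(header.get("NPOINTS", len(ys))))
        if npoints != len(ys):
            raise SpectrumParseError(
                f"{path}: ##NPOINTS={npoints} but {len(ys)} ordinates found"
            )
        firstx = float(header["FIRSTX"]) * xfactor * xscale
        lastx = float(header["LASTX"]) * xfactor * xscale
        freq = np.linspace(firstx, lastx, npoints)
        absorb = np.array(ys) * yfactor
    else:
        vals: list[float] = []
        for lineno, line in raw:
            vals.extend(_jcamp_numbers(line, path, lineno))
        if len(vals) % 2:
            raise SpectrumParseError(f"{path}: odd number of XYPOINTS values")
        arr = np.array(vals).reshape(-1, 2)
        freq = arr[:, 0] * xfactor * xscale
        absorb = arr[:, 1] * yfactor
        if "NPOINTS" in header and int(float(header["NPOINTS"])) != len(freq):
            raise SpectrumParseError(
                f"{path}: ##NPOINTS={header['NPOINTS']} but {len(freq)} points found"
            )
    if "TITLE" in header and header["TITLE"]:
        meta.setdefault("name", header["TITLE"])
    return freq, absorb, meta


def _scan_block_kind(path: Path) -> bool:
    """True if the (single) data block in ``path`` is XYDATA, False for XYPOINTS."""
    with open(path, "r", encoding="utf-8") as fh:
        kind = None
        for line in fh:
            u = line.upper().replace(" ", "")
            if u.startswith("##XYDATA="):
                kind = True
            elif u.startswith("##XYPOINTS="):
                kind = False
    if kind is None:
        raise SpectrumParseError(f"{path}: no XYDATA/XYPOINTS block found")
    return kind


def write_spectrum(s: Spectrum, path, format: str | None = None) -> None:
    """Write ``s`` to ``path`` as CSV or minimal JCAMP-DX (XYPOINTS)."""
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in (".jdx", ".dx") else "csv"
    name = s.name
    if not name:
        name = "unnamed"
        logger.warning("writing spectrum with empty name; using placeholder 'unnamed'")
    if format == "csv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# name = {name}\n")
            for key, value in s.meta.items():
                fh.write(f"# {key} = {value}\n")
            fh.write("freq_thz,absorbance\n")
            for f, a in zip(s.freq, s.absorbance):
                fh.write(f"{f:.17g},{a:.17g}\n")
    elif format == "jcamp":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"##TITLE={name}\n")
            fh.write("##JCAMP-DX=4.24\n")
            fh.write("##DATA TYPE=THZ ABSORBANCE SPECTRUM\n")
            fh.write("##XUNITS=THZ\n##YUNITS=ABSORBANCE\n")
            fh.write("##XFACTOR=1.0\n##YFACTOR=1.0\n")
            fh.write(f"##FIRSTX={s.freq[0]:.17g}\n##LASTX={s.freq[-1]:.17g}\n")
            fh.write(f"##NPOINTS={len(s.freq)}\n")
            for key, value in s.meta.items():
                fh.write(f"##$META_{key}={value}\n")
            fh.write("##XYPOINTS=(XY..XY)\n")
            for f, a in zip(s.freq, s.absorbance):
                fh.write(f"{f:.17g}, {a:.17g}\n")
            fh.write("##END=\n")
    else:
        raise ValueError(f"unknown spectrum format {format!r}")


# ---------------------------------------------------------------------------
# peak-list I/O
# ---------------------------------------------------------------------------

def read_peak_list(path, analyte: str | None = None, source: str = "experimental") -> PeakList:
    """Read a peak list from a CSV/TSV file with columns freq, intensity[, label]."""
    path = Path(path)
    peaks = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.strip()
            if not line or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.replace("\t", ",").split(",") if c.strip()]
            try:
                freq = float(cells[0])
            except (ValueError, IndexError):
                if lineno == 1 or not peaks:
                    continue  # tolerate a header row
                raise SpectrumParseError(f"{path}: bad peak row", line=lineno) from None
            intensity = float(cells[1]) if len(cells) > 1 else 1.0
            label = cells[2] if len(cells) > 2 else "none"
            peaks.append(Peak(freq, intensity, label))
    peaks.sort(key=lambda p: p.freq)
    return PeakList(analyte or path.stem, source, peaks)


def write_peak_list(pl: PeakList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("freq_thz,intensity,label\n")
        for p in pl:
            fh.write(f"{p.freq:.17g},{p.intensity:.17g},{p.label}\n")


# ---------------------------------------------------------------------------
# database loading
# ---------------------------------------------------------------------------

def load_database(root, manifest=None, peak_params=None) -> SpectralDatabase:
    """Load a spectral database from a directory of spectrum files.

    Without a manifest every ``*.csv``/``*.jdx``/``*.dx`` file under ``root``
    becomes one entry named after the file stem (or the ``name`` metadata in
    the file).  ``manifest`` may be a path to a YAML file, or a mapping,
    of the form ``name: {spectrum: file[, peaks: file]}`` (a bare string value
    is shorthand for the spectrum file).  Entries without a stored peak list
    get one computed by :func:`thzssm.preprocess.find_peaks` with default
    parameters.
    """
    from .preprocess import find_peaks  # deferred to avoid import cycle

    root = Path(root)
    if not root.is_dir():
        raise DatabaseError(f"database root {root} is not a directory")

    plan: list[tuple[str, Path, Path | None]] = []
    if manifest is not None:
        if not isinstance(manifest, dict):
            with open(manifest, "r", encoding="utf-8") as fh:
                manifest = yaml.safe_load(fh)
        if not isinstance(manifest, dict):
            raise DatabaseError("database manifest must be a mapping name -> files")
        for name, value in manifest.items():
            if isinstance(value, str):
                plan.append((str(name), root / value, None))
            else:
                peaks = value.get("peaks")
                plan.append(
                    (str(name), root / value["spectrum"], root / peaks if peaks else None)
                )
    else:
        files = sorted(
            p for p in root.iterdir()
            if p.suffix.lower() in (".csv", ".jdx", ".dx") and p.is_file()
            and p.name != "manifest.yaml"
        )
        for p in files:
            plan.append((None, p, None))

    entries: dict[str, DatabaseEntry] = {}
    for name, spath, ppath in plan:
        spec = read_spectrum(spath)
        label = name or spec.name
        spec.name = label
        if label in entries:
            raise DatabaseError(f"duplicate analyte name {label!r} in database {root}")
        if ppath is not None:
            peaks = read_peak_list(ppath, analyte=label)
        else:
            peaks = find_peaks(spec, peak_params)
        peaks.analyte = label
        entries[label] = DatabaseEntry(spec, peaks)
    if not entries:
        raise DatabaseError(f"no spectrum files found under {root}")
    return SpectralDatabase(entries, provenance=f"loaded from {root}")


# ---------------------------------------------------------------------------
# packaged fixture: fingerprint peaks of the eight fentanyl analogs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Row:
    analyte: str
    dft_freq: float
    dft_label: str
    exp_freq: float
    shift: float  # tabulated value, as printed (not recomputed)
    mode: str


@dataclass(frozen=True)
class AnalogPeaks:
    dft: PeakList
    experimental: PeakList


@lru_cache(maxsize=1)
def table1_rows() -> tuple[Table1Row, ...]:
    """The packaged peak inventory, row by row."""
    text = resources.files("thzssm.data").joinpath("table1_peaks.tsv").read_text("utf-8")
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        analyte, dft_f, label, exp_f, shift, mode = line.split("\t")
        rows.append(
            Table1Row(analyte, float(dft_f), label, float(exp_f), float(shift), mode)
        )
    return tuple(rows)


@lru_cache(maxsize=1)
def builtin_table1() -> dict[str, AnalogPeaks]:
    """Fingerprint peak lists of the eight fentanyl analogs.

    Returns a mapping from full analyte name to its DFT and experimental
    :class:`PeakList`.  DFT peaks carry the tabulated strength label and a
    relative intensity from :data:`STRENGTH_AMPLITUDES`; experimental peaks
    are unlabeled and inherit the intensity of the same row's DFT peak
    (the inventory gives no experimental intensities).
    """
    by_analyte: dict[str, list[Table1Row]] = {}
    for row in table1_rows():
        by_analyte.setdefault(row.analyte, []).append(row)
    out = {}
    for analyte, rows in by_analyte.items():
        dft = PeakList(
            analyte,
            "dft",
            [Peak(r.dft_freq, STRENGTH_AMPLITUDES[r.dft_label], r.dft_label) for r in rows],
        )
        exp = PeakList(
            analyte,
            "experimental",
            [Peak(r.exp_freq, STRENGTH_AMPLITUDES[r.dft_label], "none") for r in rows],
        )
        out[analyte] = AnalogPeaks(dft=dft, experimental=exp)
    return out
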