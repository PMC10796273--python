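"""CSV readers/writers for the pipeline's tabular interfaces.

Every schema is comma-separated UTF-8 with a mandatory header and '.' as the
decimal mark; anything else is rejected loudly rather than guessed at.
Row numbers in error messages are 1-based data rows (the header is row 0).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParseError, SchemaError
from .kinetics import ScanRateStudy, Voltammogram
from .spectra import Spectrum

__all__ = [
    "SCHEMAS",
    "read_table",
    "read_voltammogram_csv",
    "read_scan_rate_study",
    "read_spectrum_csv",
    "read_multiframe_spectrum_csv",
    "write_voltammogram_csv",
    "write_spectrum_csv",
]

#: column name -> dtype ("float", "int", "str") per named schema
SCHEMAS: dict[str, dict[str, str]] = {
    "voltammogram": {"potential_V": "float", "current_A": "float"},
    "manifest": {"file": "str", "scan_rate_V_per_s": "float", "label": "str"},
    "metabolic": {
        "cell_line": "str",
        "diameter_nm": "float",
        "linker_kda": "float",
        "time_h": "float",
        "activity_fraction": "float",
        "replicate": "int",
    },
    "spectrum": {"wavelength_nm": "float", "intensity": "float"},
}


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and type-check a CSV against a named schema.

    Raises
    ------
    SchemaError
        If the header is missing a required column (named in the message).
    ParseError
        If a cell cannot be converted, citing its 1-based data row.
    InputError
        For an unknown schema or an empty file.
    """
    if schema_name not in SCHEMAS:
        raise InputError(f"unknown schema '{schema_name}'; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, encoding="utf-8", skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty file: {path}") from None
    if raw.empty:
        raise InputError(f"{path}: no data rows")

    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema '{schema_name}'")

    out = {}
    for col, kind in schema.items():
        series = raw[col]
        if kind == "str":
            out[col] = series.astype(str)
            continue
        converted = pd.to_numeric(series, errors="coerce")
        bad = converted.isna() & series.notna()
        if bad.any() or converted.isna().any():
            row = int(np.nonzero((converted.isna()).to_numpy())[0][0]) + 1
            raise ParseError(
                f"{path}: non-numeric value {series.iloc[row - 1]!r} in column "
                f"'{col}' at data row {row}"
            )
        out[col] = converted.astype(float if kind == "float" else int)
    frame = pd.DataFrame(out)
    frame.index = raw.index
    return frame


def read_voltammogram_csv(path, scan_rate: float, label: str = "",
                          temperature_K: float = 298.15) -> Voltammogram:
    table = read_table(path, "voltammogram")
    return Voltammogram(
        potential=table["potential_V"].to_numpy(),
        current=table["current_A"].to_numpy(),
        scan_rate=scan_rate,
        label=label or Path(path).stem,
        temperature_K=temperature_K,
    )


def read_scan_rate_study(manifest_path) -> ScanRateStudy:
    """Assemble a study from a manifest CSV: `file,scan_rate_V_per_s,label`.

    File paths in the manifest are resolved relative to the manifest itself.
    """
    manifest_path = Path(manifest_path)
    manifest = read_table(manifest_path, "manifest")
    vgrams = []
    for _, row in manifest.iterrows():
        vg_path = Path(row["file"])
        if not vg_path.is_absolute():
            vg_path = manifest_path.parent / vg_path
        vgrams.append(
            read_voltammogram_csv(vg_path, float(row["scan_rate_V_per_s"]), str(row["label"]))
        )
    return ScanRateStudy(voltammograms=vgrams, shared_label=manifest_path.stem)


def read_spectrum_csv(path, kind: str = "scattering", label: str = "") -> Spectrum:
    table = read_table(path, "spectrum")
    return Spectrum(
        wavelength=table["wavelength_nm"].to_numpy(),
        intensity=table["intensity"].to_numpy(),
        kind=kind,
        label=label or Path(path).stem,
    )


def read_multiframe_spectrum_csv(path, kind: str = "scattering", label: str = "") -> Spectrum:
    """Average a multi-frame acquisition: wavelength column + one column per frame."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise InputError(f"empty file: {path}") from None
    if "wavelength_nm" not in raw.columns:
        raise SchemaError(f"{path}: missing column(s) ['wavelength_nm'] for multi-frame spectrum")
    frames = [c for c in raw.columns if c != "wavelength_nm"]
    if not frames:
        raise SchemaError(f"{path}: no frame columns beside wavelength_nm")
    return Spectrum(
        wavelength=raw["wavelength_nm"].to_numpy(dtype=float),
        intensity=raw[frames].to_numpy(dtype=float).mean(axis=1),
        kind=kind,
        label=label or path.stem,
    )


def write_voltammogram_csv(vgram: Voltammogram, path) -> None:
    pd.DataFrame(
        {"potential_V": vgram.potential, "current_A": vgram.current}
    ).to_csv(path, index=False)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength, "intensity": spectrum.intensity}
    ).to_csv(path, index=False)
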