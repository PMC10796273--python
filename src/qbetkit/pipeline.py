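"""End-to-end orchestration: config validation, stage execution, reporting.

A single config (YAML or JSON) enables any subset of four stages —
kinetics, qbet (charging rates + barrier fit), spectral, feasibility — each
fed either by a synthetic generator block or by CSV inputs.  The rate
constant found by the kinetics stage is threaded into the feasibility stage
when both run.  With a fixed seed the emitted JSON report is byte-identical
between runs except for its timestamp.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as qio
from .errors import ConfigurationError, QbetError
from .kinetics import KineticsResult, analyze_study
from .simulate import (
    Band,
    CVSimParams,
    MetabolicSimParams,
    SpectrumSimParams,
    simulate_metabolic_dataset,
    simulate_scan_rate_study,
    simulate_spectrum,
)
from .spectra import (
    detect_quantized_features,
    difference_spectrum,
    soret_shift_call,
)
from .tunneling import (
    aggregate_charging_rates,
    classical_feasibility,
    fit_barrier_decay,
    linker_length_from_mw,
    max_hop_distance,
    round_to_sig_figs,
)

__all__ = [
    "RunConfig",
    "ReportBundle",
    "StageError",
    "EXIT_CODES",
    "load_config",
    "run_full_analysis",
    "write_report",
    "read_report",
]

EXIT_CODES = {"config": 2, "kinetics": 3, "qbet": 4, "feasibility": 4, "spectral": 5, "io": 6}

STAGES = ("kinetics", "qbet", "spectral", "feasibility")


class StageError(QbetError):
    """Wraps a stage failure with its exit code and any partial results."""

    def __init__(self, stage: str, cause: Exception, partial: "ReportBundle | None" = None):
        self.stage = stage
        self.exit_code = EXIT_CODES.get(stage, 1)
        self.partial = partial
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    raw: dict
    path: Path | None = None

    @property
    def seed(self) -> int | None:
        return self.raw.get("seed")

    def stage(self, name: str) -> dict:
        return self.raw.get(name) or {}

    def enabled(self, name: str) -> bool:
        return bool(self.stage(name).get("enabled", False))

    def validate(self) -> None:
        """Check paths and cross-field requirements before any stage runs."""
        if not any(self.enabled(s) for s in STAGES):
            raise ConfigurationError("no stage is enabled")
        uses_synthetic = any(
            self.enabled(s) and "synthetic" in self.stage(s) for s in STAGES
        )
        if uses_synthetic and self.seed is None:
            raise ConfigurationError("a 'seed' is required when any synthetic stage is enabled")
        base = self.path.parent if self.path else Path(".")
        for stage_name in STAGES:
            cfg = self.stage(stage_name)
            if not cfg.get("enabled"):
                continue
            for key in ("manifest", "table", "minuend", "subtrahend", "soret_pre", "soret_post"):
                if key in cfg:
                    p = Path(cfg[key])
                    if not p.is_absolute():
                        p = base / p
                    if not p.exists():
                        raise ConfigurationError(f"{stage_name}.{key}: no such file {p}")
        if self.enabled("kinetics") and self.stage("kinetics").get("D_coeff") is None:
            raise ConfigurationError(
                "kinetics.D_coeff is required: the diffusion coefficient has no default"
            )

    def resolve(self, relpath) -> Path:
        p = Path(relpath)
        if not p.is_absolute() and self.path is not None:
            p = self.path.parent / p
        return p


@dataclass
class ReportBundle:
    """JSON-serialisable results of every stage plus provenance."""

    kinetics: dict = field(default_factory=lambda: {"status": "skipped"})
    charging: list | dict = field(default_factory=lambda: {"status": "skipped"})
    tunnelling: dict = field(default_factory=lambda: {"status": "skipped"})
    spectral: dict = field(default_factory=lambda: {"status": "skipped"})
    feasibility: dict = field(default_factory=lambda: {"status": "skipped"})
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config file and validate it."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such config file: {path}")
    text = path.read_text(encoding="utf-8")
    raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    cfg = RunConfig(raw=raw, path=path)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _kinetics_to_dict(res: KineticsResult) -> dict:
    def _fit(f):
        if f is None:
            return None
        d = dataclasses.asdict(f)
        d["warnings"] = list(d["warnings"])
        return d

    return {
        "status": "ok",
        "psi_per_rate": [list(map(float, row)) for row in res.psi_per_rate],
        "k0_per_rate": [list(map(float, row)) for row in res.k0_per_rate],
        "k0_mean": res.k0_mean,
        "k0_sd": res.k0_sd,
        "alpha_ct_used": res.alpha_ct_used,
        "D_used": res.D_used,
        "n_used": res.n_used,
        "temperature_K": res.temperature_K,
        "warnings": list(res.warnings),
        "alpha_fit_cathodic": _fit(res.alpha_fit_cathodic),
        "alpha_fit_anodic": _fit(res.alpha_fit_anodic),
    }


def _run_kinetics(config: RunConfig) -> dict:
    cfg = config.stage("kinetics")
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        rates = syn.pop("rates")
        params = CVSimParams(seed=config.seed, D_coeff=cfg["D_coeff"], **syn)
        study = simulate_scan_rate_study(params, rates)
    elif "manifest" in cfg:
        study = qio.read_scan_rate_study(config.resolve(cfg["manifest"]))
    else:
        raise ConfigurationError("kinetics stage needs either 'synthetic' or 'manifest'")
    result = analyze_study(
        study,
        D_coeff=cfg["D_coeff"],
        n_electrons=int(cfg.get("n_electrons", 1)),
        alpha_ct=cfg.get("alpha_ct"),
    )
    return _kinetics_to_dict(result)


def _run_qbet(config: RunConfig) -> tuple[list, dict]:
    cfg = config.stage("qbet")
    convention = cfg.get("length_convention", "contour")
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        for key in ("linker_masses", "diameters", "times"):
            if key in syn:
                syn[key] = tuple(syn[key])
        params = MetabolicSimParams(seed=config.seed, **syn)
        dataset = simulate_metabolic_dataset(params, length_convention=convention)
        table = dataset.table
    elif "table" in cfg:
        table = qio.read_table(config.resolve(cfg["table"]), "metabolic")
        table = table.assign(
            linker_length_nm=[
                linker_length_from_mw(m, convention=convention if convention != "custom" else "custom")
                for m in table["linker_kda"]
            ]
        )
    else:
        raise ConfigurationError("qbet stage needs either 'synthetic' or 'table'")

    rates = aggregate_charging_rates(table)
    charging = [
        {
            "condition": list(r.condition),
            "r_d": r.r_d,
            "se": r.se,
            "n_replicates": r.n_replicates,
            "linker_length_nm": r.linker_length,
            "supranormal": r.supranormal,
            "usable_for_fit": r.usable_for_fit,
        }
        for r in rates
    ]
    fit = fit_barrier_decay(rates)
    tunnelling = {
        "status": "ok",
        "alpha_loc": fit.alpha_loc,
        "beta": fit.beta,
        "alpha_se": fit.alpha_se,
        "beta_se": fit.beta_se,
        "r_squared": fit.r_squared,
        "n_points": fit.n_points,
        "method": fit.method,
        "loglinear_alpha": fit.loglinear_alpha,
        "loglinear_beta": fit.loglinear_beta,
        "warnings": list(fit.warnings),
    }
    return charging, tunnelling


def _spectral_pair(config: RunConfig, cfg: dict):
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        if "bands" in syn:
            base_bands = tuple(Band(*b) for b in syn["bands"])
        else:
            base_bands = SpectrumSimParams().bands
        dip = syn.get("dip")
        common = {
            k: v for k, v in syn.items() if k in ("baseline", "step", "noise_sd")
        }
        if "wavelength_range" in syn:
            common["wavelength_range"] = tuple(syn["wavelength_range"])
        sub = simulate_spectrum(
            SpectrumSimParams(bands=base_bands, seed=config.seed, label="reference", **common)
        )
        minuend_bands = base_bands
        if dip is not None:
            centre, width, depth = dip
            minuend_bands = base_bands + (Band(centre, width, depth, sign=-1),)
        minu = simulate_spectrum(
            SpectrumSimParams(
                bands=minuend_bands, seed=config.seed + 1, label="functionalized", **common
            )
        )
        return minu, sub
    minu = qio.read_spectrum_csv(config.resolve(cfg["minuend"]), label="minuend")
    sub = qio.read_spectrum_csv(config.resolve(cfg["subtrahend"]), label="subtrahend")
    return minu, sub


def _run_spectral(config: RunConfig) -> dict:
    cfg = config.stage("spectral")
    out: dict = {"status": "ok"}
    minu, sub = _spectral_pair(config, cfg)
    ds = difference_spectrum(minu, sub, normalization=cfg.get("normalization", "max"))
    feats = detect_quantized_features(
        ds, min_prominence=float(cfg.get("dip_prominence", 0.05)),
        polarity=cfg.get("polarity", "dip"),
    )
    out["features"] = [dataclasses.asdict(f) for f in feats]
    out["difference"] = {
        "minuend": ds.minuend_label,
        "subtrahend": ds.subtrahend_label,
        "normalization": ds.normalization,
        "n_points": int(ds.wavelength.size),
    }
    if "soret_pre" in cfg and "soret_post" in cfg:
        pre = qio.read_spectrum_csv(config.resolve(cfg["soret_pre"]), kind="absorbance")
        post = qio.read_spectrum_csv(config.resolve(cfg["soret_post"]), kind="absorbance")
        call = soret_shift_call(pre, post, threshold=float(cfg.get("soret_threshold_nm", 2.0)))
        out["redox_call"] = {
            "soret_pre_nm": call.soret_pre,
            "soret_post_nm": call.soret_post,
            "shift_nm": call.shift,
            "call": call.call,
            "threshold_nm": call.threshold,
        }
    return out


def _run_feasibility(config: RunConfig, kinetics: dict) -> dict:
    cfg = config.stage("feasibility")
    k0 = cfg.get("k0")
    if k0 is None:
        if kinetics.get("status") != "ok":
            raise ConfigurationError(
                "feasibility.k0 not given and the kinetics stage did not run"
            )
        k0 = kinetics["k0_mean"]
    frequency = float(cfg.get("frequency_hz", 3.0e6))
    if "linker_length_nm" in cfg:
        length = float(cfg["linker_length_nm"])
    else:
        length = linker_length_from_mw(float(cfg.get("linker_kda", 2.0)))
    d_max = max_hop_distance(float(k0), frequency)
    report = classical_feasibility(d_max, length, k0=float(k0), frequency=frequency)
    return {
        "status": "ok",
        "k0_cm_per_s": report.k0,
        "frequency_hz": report.frequency,
        "d_max_nm": report.d_max,
        "d_max_nm_1sf": round_to_sig_figs(report.d_max, 1),
        "linker_length_nm": report.linker_length,
        "classical_possible": report.classical_possible,
    }


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute enabled stages in order; raise :class:`StageError` on failure.

    Stage order: kinetics -> qbet -> spectral -> feasibility, with the
    kinetics k0_mean threaded into feasibility when the latter gives no
    explicit k0.  Skipped stages are recorded as such, never silently
    dropped.
    """
    try:
        config.validate()
    except QbetError as err:
        raise StageError("config", err) from err

    from . import __version__

    bundle = ReportBundle(
        provenance={
            "config": config.raw,
            "seed": config.seed,
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
    )
    try:
        if config.enabled("kinetics"):
            bundle.kinetics = _run_kinetics(config)
    except QbetError as err:
        raise StageError("kinetics", err, partial=bundle) from err
    try:
        if config.enabled("qbet"):
            bundle.charging, bundle.tunnelling = _run_qbet(config)
    except QbetError as err:
        raise StageError("qbet", err, partial=bundle) from err
    try:
        if config.enabled("spectral"):
            bundle.spectral = _run_spectral(config)
    except QbetError as err:
        raise StageError("spectral", err, partial=bundle) from err
    try:
        if config.enabled("feasibility"):
            bundle.feasibility = _run_feasibility(config, bundle.kinetics)
    except QbetError as err:
        raise StageError("feasibility", err, partial=bundle) from err
    return bundle


REPORT_SCHEMA_VERSION = 1


def write_report(bundle: ReportBundle, out_dir, failed_at: str | None = None) -> Path:
    """Write the JSON report plus per-stage CSV extracts; return the JSON path.

    Keys are sorted for diff-stability; the schema version is embedded.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = bundle.to_dict()
    doc["schema_version"] = REPORT_SCHEMA_VERSION
    if failed_at is not None:
        doc["failed_at"] = failed_at
    path = out_dir / "report.json"
    path.write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n", encoding="utf-8")

    if isinstance(bundle.kinetics, dict) and bundle.kinetics.get("status") == "ok":
        pd.DataFrame(
            bundle.kinetics["psi_per_rate"], columns=["scan_rate_V_per_s", "delta_Ep_V", "psi"]
        ).assign(k0_cm_per_s=[k for _, k in bundle.kinetics["k0_per_rate"]]).to_csv(
            out_dir / "kinetics_per_rate.csv", index=False
        )
    if isinstance(bundle.charging, list) and bundle.charging:
        pd.DataFrame(
            [
                {
                    "cell_line": c["condition"][0],
                    "diameter_nm": c["condition"][1],
                    "linker_kda": c["condition"][2],
                    "linker_length_nm": c["linker_length_nm"],
                    "r_d_per_h": c["r_d"],
                    "se_per_h": c["se"],
                    "n_replicates": c["n_replicates"],
                }
                for c in bundle.charging
            ]
        ).to_csv(out_dir / "charging_rates.csv", index=False)
    if isinstance(bundle.tunnelling, dict) and bundle.tunnelling.get("status") == "ok":
        import numpy as np

        lengths = [c["linker_length_nm"] for c in bundle.charging] if bundle.charging else [5, 40]
        grid = np.linspace(min(lengths), max(lengths), 50)
        curve = bundle.tunnelling["beta"] * np.exp(-bundle.tunnelling["alpha_loc"] * grid)
        pd.DataFrame({"linker_length_nm": grid, "r_d_fit_per_h": curve}).to_csv(
            out_dir / "tunnelling_curve.csv", index=False
        )
    if isinstance(bundle.spectral, dict) and bundle.spectral.get("status") == "ok":
        pd.DataFrame(bundle.spectral["features"]).to_csv(
            out_dir / "spectral_features.csv", index=False
        )
    return path


def read_report(path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
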