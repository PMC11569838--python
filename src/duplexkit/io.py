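"""Delimited-text readers and writers for every stage, plus the pipeline.

All tabular I/O is plain delimited text (comma by default, tab accepted),
decimal dot, '#' comment lines skipped, header row required.  Dialects:

* ``melting``:  temperature_C, absorbance [, reference_absorbance]
* ``series``:   Ct_uM, Tm_C [, Tm_err_C]
* ``spectra``:  wavelength_nm, control, then one column per sample named by
  its complement concentration in μM
* ``bands``:    substrate, replicate, time_min, intensity
* ``mobility``: lane_label, band_position_mm (or mobility_au)
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, ParseError, SchemaError
from .excision import ExcisionTimecourse
from .meltfit import MeltingCurve
from .thermo import StrandConcentration
from .titration import SpectrumSeries
from .vanthoff import ConcentrationSeries, SeriesPoint

log = logging.getLogger("duplexkit")

_DIALECTS = ("melting", "series", "spectra", "bands", "mobility")

_REQUIRED = {
    "melting": ["temperature_C", "absorbance"],
    "series": ["Ct_uM", "Tm_C"],
    "bands": ["substrate", "replicate", "time_min", "intensity"],
}


def _read_frame(path) -> pd.DataFrame:
    text = Path(path).read_text()
    kept = [ln for ln in text.splitlines() if not ln.lstrip().startswith("#")]
    if not kept:
        raise SchemaError(f"{path}: empty file")
    sep = "\t" if "\t" in kept[0] else ","
    return pd.read_csv(_io.StringIO("\n".join(kept)), sep=sep, dtype=str,
                       skipinitialspace=True)


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} "
            f"in column {col!r}, data row {row + 1}"
        )
    return out.to_numpy(dtype=float)


def read_table(path, dialect: str, **metadata):
    """Read one stage-input file and return the validated domain object.

    ``metadata`` supplies the fields the file itself does not carry
    (``ct_uM``, ``wavelength``, ``ramp``, ``label`` for melting curves;
    ``mode``, ``modified_conc_uM``, ``fixed_wavelength`` for spectra).
    """
    if dialect not in _DIALECTS:
        raise ConfigError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")
    df = _read_frame(path)

    if dialect == "melting":
        _require(df, _REQUIRED["melting"], path)
        ref = None
        if "reference_absorbance" in df.columns:
            ref = _numeric(df, "reference_absorbance", path)
        return MeltingCurve(
            temperatures=_numeric(df, "temperature_C", path),
            absorbances=_numeric(df, "absorbance", path),
            reference_absorbances=ref,
            ct=StrandConcentration.from_micromolar(float(metadata.get("ct_uM", 20.0))),
            wavelength=float(metadata.get("wavelength", 260.0)),
            ramp=metadata.get("ramp", "heating"),
            label=metadata.get("label", str(path)),
        )

    if dialect == "series":
        _require(df, _REQUIRED["series"], path)
        ct = _numeric(df, "Ct_uM", path) * 1e-6
        tm = _numeric(df, "Tm_C", path)
        err = (
            _numeric(df, "Tm_err_C", path)
            if "Tm_err_C" in df.columns
            else [None] * len(tm)
        )
        points = [
            SeriesPoint(ct=c, tm_C=t, tm_err_C=None if e is None else float(e))
            for c, t, e in zip(ct, tm, err)
        ]
        return ConcentrationSeries(points=points, label=metadata.get("label", str(path)))

    if dialect == "spectra":
        _require(df, ["wavelength_nm", "control"], path)
        sample_cols = [
            c for c in df.columns if c not in ("wavelength_nm", "control")
        ]
        if not sample_cols:
            raise SchemaError(f"{path}: no sample columns (named by conc in uM)")
        try:
            concs = sorted((float(c), c) for c in sample_cols)
        except ValueError as exc:
            raise SchemaError(
                f"{path}: sample columns must be named by complement "
                f"concentration in uM ({exc})"
            ) from None
        return SpectrumSeries(
            wavelengths=_numeric(df, "wavelength_nm", path),
            complement_concs=np.array([c * 1e-6 for c, _ in concs]),
            intensities=np.array([_numeric(df, name, path) for _, name in concs]),
            control=_numeric(df, "control", path),
            mode=metadata.get("mode", "absorbance"),
            modified_conc=float(metadata.get("modified_conc_uM", 5.4)) * 1e-6,
            fixed_wavelength=metadata.get("fixed_wavelength"),
            label=metadata.get("label", str(path)),
        )

    if dialect == "bands":
        _require(df, _REQUIRED["bands"], path)
        times = _numeric(df, "time_min", path)
        intens = _numeric(df, "intensity", path)
        courses = []
        for (substrate, rep), group in df.assign(
            _t=times, _i=intens
        ).groupby(["substrate", "replicate"], sort=True):
            order = np.argsort(group["_t"].to_numpy())
            courses.append(
                ExcisionTimecourse(
                    substrate=str(substrate),
                    times=group["_t"].to_numpy()[order],
                    intensities=group["_i"].to_numpy()[order],
                    replicate_id=str(rep),
                )
            )
        return courses

    # mobility
    _require(df, ["lane_label"], path)
    value_col = next(
        (c for c in ("band_position_mm", "mobility_au") if c in df.columns), None
    )
    if value_col is None:
        raise SchemaError(
            f"{path}: need a 'band_position_mm' or 'mobility_au' column"
        )
    values = _numeric(df, value_col, path)
    return dict(zip(df["lane_label"].astype(str), values))


def write_melting_curve(path, curve: MeltingCurve) -> None:
    cols = {"temperature_C": curve.temperatures, "absorbance": curve.absorbances}
    if curve.reference_absorbances is not None:
        cols["reference_absorbance"] = curve.reference_absorbances
    _write_frame(path, pd.DataFrame(cols))


def write_series(path, series: ConcentrationSeries) -> None:
    rows = {
        "Ct_uM": [p.ct * 1e6 for p in series.points],
        "Tm_C": [p.tm_C for p in series.points],
    }
    if all(p.tm_err_C is not None for p in series.points):
        rows["Tm_err_C"] = [p.tm_err_C for p in series.points]
    _write_frame(path, pd.DataFrame(rows))


def write_spectra(path, series: SpectrumSeries) -> None:
    cols = {"wavelength_nm": series.wavelengths, "control": series.control}
    for conc, spectrum in zip(series.complement_concs, series.intensities):
        cols[f"{conc * 1e6:g}"] = spectrum
    _write_frame(path, pd.DataFrame(cols))


def write_bands(path, courses: list[ExcisionTimecourse]) -> None:
    rows = []
    for tc in courses:
        for t, i in zip(tc.times, tc.intensities):
            rows.append(
                {"substrate": tc.substrate, "replicate": tc.replicate_id,
                 "time_min": t, "intensity": i}
            )
    _write_frame(path, pd.DataFrame(rows))


def _write_frame(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


_RUNCONFIG_KEYS = {
    "melting_path", "series_path", "spectra_path", "bands_path", "mobility_path",
    "wavelength", "ramp_rate", "buffer", "ct_uM", "report_ct_uM",
    "reference_lane", "numerator", "denominator", "n_boot", "rescale",
    "out_dir", "verbosity", "seed", "mode", "modified_conc_uM",
}


@dataclass
class RunConfig:
    """Flat key=value run configuration; unknown keys are rejected."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - _RUNCONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        return cls(values=values)

    def get(self, key, default=None):
        return self.values.get(key, default)


def write_provenance(out_dir, cfg: RunConfig) -> None:
    lines = [f"duplexkit_version={__version__}"]
    lines += [f"{k}={v}" for k, v in sorted(cfg.values.items())]
    Path(out_dir, "provenance.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage the config provides inputs for.

    Stages: melt-fit (melting_path), van 't Hoff + summary (series_path),
    bend (mobility_path), titrate (spectra_path), excision (bands_path).
    A failing stage is recorded and the others continue; the caller decides
    the exit code from the ``errors`` entry.  Reports are delimited text in
    ``out_dir`` plus a provenance block.
    """
    from . import excision as exc_mod
    from . import gel, meltfit, titration, vanthoff

    if not cfg.values:
        raise ConfigError("empty configuration: no stage inputs given")
    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"errors": {}}
    summary_rows = []

    if cfg.get("melting_path"):
        try:
            curve = read_table(cfg.get("melting_path"), "melting",
                               ct_uM=float(cfg.get("ct_uM", 20.0)))
            fit = meltfit.fit_melting_curve(meltfit.preprocess_curve(curve))
            results["melt_fit"] = fit
            log.info(
                "melt-fit: Tm=%.2f degC dH=%.1f kcal/mol h=%.2f%% ssr=%.3g "
                "converged=%s", fit.tm, fit.params.dH_kcal, fit.hypochromicity,
                fit.ssr, fit.converged,
            )
            pd.DataFrame([{
                "tm_C": fit.tm, "dH_kcal": fit.params.dH_kcal,
                "dS_cal": fit.params.dS, "hypochromicity_pct": fit.hypochromicity,
                "ssr_AU2": fit.ssr, "converged": fit.converged,
            }]).pipe(lambda df: _write_frame(out_dir / "melt_fit.csv", df))
        except Exception as err:  # noqa: BLE001 - stage isolation
            log.error("melt-fit stage failed: %s", err)
            results["errors"]["melt_fit"] = err

    if cfg.get("series_path"):
        try:
            series = read_table(cfg.get("series_path"), "series")
            vh = vanthoff.fit_vant_hoff(series)
            row = vanthoff.summarize_duplex(
                vh,
                StrandConcentration.from_micromolar(
                    float(cfg.get("report_ct_uM", 20.0))
                ),
                label=series.label,
            )
            results["vant_hoff"] = vh
            summary_rows.append(row)
            log.info("vanthoff: dH=%.1f kcal dS=%.0f cal dG37=%.2f kcal r2=%.5f",
                     row["dH_kcal_per_mol"], row["dS_cal_per_mol_K"],
                     row["dG37_kcal_per_mol"], row["r_squared"])
            _write_frame(out_dir / "vant_hoff.csv", pd.DataFrame([row]))
        except Exception as err:  # noqa: BLE001
            log.error("vanthoff stage failed: %s", err)
            results["errors"]["vant_hoff"] = err

    if cfg.get("mobility_path"):
        try:
            lanes = read_table(cfg.get("mobility_path"), "mobility")
            ref = cfg.get("reference_lane")
            if ref is None:
                raise ConfigError("mobility stage requires reference_lane")
            pairs = gel.relative_mobility(lanes, ref)
            bends = {lbl: gel.bend_angle(p) for lbl, p in pairs.items()}
            results["bend"] = bends
            for lbl, b in bends.items():
                log.info("bend: %s interior=%.2f deg (ratio %.5f)",
                         lbl, b.interior_angle, b.ratio)
            _write_frame(out_dir / "bend.csv", pd.DataFrame([
                {"lane": lbl, "mobility_ratio": b.ratio,
                 "interior_angle_deg": b.interior_angle,
                 "deflection_deg": b.deflection}
                for lbl, b in bends.items()
            ]))
        except Exception as err:  # noqa: BLE001
            log.error("bend stage failed: %s", err)
            results["errors"]["bend"] = err

    if cfg.get("spectra_path"):
        try:
            series = read_table(
                cfg.get("spectra_path"), "spectra",
                mode=cfg.get("mode", "absorbance"),
                modified_conc_uM=float(cfg.get("modified_conc_uM", 5.4)),
            )
            if series.mode == "absorbance":
                summary = titration.hypochromic_effect(series)
                results["titration"] = summary
                log.info("titrate: 495-nm hypochromic effect %.1f%% (monotone=%s)",
                         summary.hypochromic_effect_pct, summary.monotone_flag)
                _write_frame(out_dir / "titration.csv", pd.DataFrame([{
                    "hypochromic_effect_pct": summary.hypochromic_effect_pct,
                    "monotone": summary.monotone_flag,
                    "direction": summary.direction,
                }]))
            else:
                q = titration.quench_fraction(series)
                results["titration"] = q
                log.info("titrate: final quench fraction %.3f", q.fractions[-1])
                _write_frame(out_dir / "titration.csv", pd.DataFrame({
                    "complement_conc_uM": series.complement_concs * 1e6,
                    "quench_fraction": q.fractions,
                }))
        except Exception as err:  # noqa: BLE001
            log.error("titrate stage failed: %s", err)
            results["errors"]["titration"] = err

    if cfg.get("bands_path"):
        try:
            courses = read_table(cfg.get("bands_path"), "bands")
            num_name = cfg.get("numerator", "nFluS")
            den_name = cfg.get("denominator", "nFluL")
            rescale = str(cfg.get("rescale", "false")).lower() == "true"
            num = [exc_mod.normalize_timecourse(tc, rescale=rescale)
                   for tc in courses if tc.substrate == num_name]
            den = [exc_mod.normalize_timecourse(tc, rescale=rescale)
                   for tc in courses if tc.substrate == den_name]
            ratio = exc_mod.efficiency_ratio(
                num, den,
                n_boot=int(cfg.get("n_boot", 2000)),
                seed=int(cfg.get("seed", 0)),
            )
            results["excision"] = ratio
            log.info("excision: %s/%s summary ratio %.3f [%.3f, %.3f]",
                     num_name, den_name, ratio.summary_ratio,
                     ratio.ci_low, ratio.ci_high)
            _write_frame(out_dir / "excision.csv", pd.DataFrame({
                "time_min": ratio.times,
                "ratio": ratio.ratio_per_time,
            }))
        except Exception as err:  # noqa: BLE001
            log.error("excision stage failed: %s", err)
            results["errors"]["excision"] = err

    if summary_rows:
        _write_frame(out_dir / "summary.csv", pd.DataFrame(summary_rows))
    write_provenance(out_dir, cfg)
    return results
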