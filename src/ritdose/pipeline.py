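"""Pipeline orchestration: configuration, validation, I/O and the full
biodistribution -> kinetics -> S-value -> dose chain.

``run_dosimetry`` chains the stages end to end: %IA conversion, per-organ
aggregation, kinetic fitting (hybrid for uptake organs, mono-exponential
otherwise), surrogate-nuclide extrapolation, cumulated-activity
integration, the Monte Carlo S-value matrix and the MIRD dose assembly,
then writes dose reports plus a machine-readable provenance block.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biodist import (
    BiodistSample,
    CumulatedActivity,
    KineticFit,
    aggregate_curve,
    cumulated_activity,
    extrapolate_to_nuclide,
    fit_hybrid,
    fit_monoexp,
)
from .mird import DoseReport, render_dose_table, tumor_to_organ_ratios
from .nuclides import load_nuclide
from .svalue import build_phantom, load_phantom_spec, svalue_matrix

__all__ = [
    "PipelineConfig",
    "StageError",
    "ValidationReport",
    "read_biodist_csv",
    "write_biodist_csv",
    "read_growth_csv",
    "read_lindmo_csv",
    "validate_inputs",
    "run_dosimetry",
]

logger = logging.getLogger(__name__)

BIODIST_COLUMNS = [
    "mouse_id",
    "organ",
    "time_h",
    "mass_g",
    "counts_cpm",
    "counter_eff_cpm_per_MBq",
    "injected_MBq",
    "count_offset_h",
]


class StageError(RuntimeError):
    """Pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs and knobs of the full dosimetry run."""

    biodist_path: str
    out_dir: str
    phantom_path: str | None = None
    nuclide_registry_path: str | None = None
    source_nuclide: str = "In-111"
    therapy_nuclides: tuple[str, ...] = ("Lu-177", "Y-90")
    hybrid_organs: tuple[str, ...] = ("tumor", "spleen")
    poly_degree: int = 2
    decay_correct_offset: bool = False
    decay_corrected_counts: bool = False
    integration: str = "full"  # "full" = [0, inf) with early flat-back; "observed"
    blood_into: str | None = "rest_of_body"
    injected_mbq: float = 3.7
    n_particles: int = 100_000
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_biodist_csv(path: str | Path) -> list[BiodistSample]:
    frame = pd.read_csv(path)
    missing = [c for c in BIODIST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        BiodistSample(
            mouse_id=str(row.mouse_id),
            organ=str(row.organ),
            time_h=float(row.time_h),
            mass_g=float(row.mass_g),
            counts_cpm=float(row.counts_cpm),
            counter_eff_cpm_per_mbq=float(row.counter_eff_cpm_per_MBq),
            injected_mbq=float(row.injected_MBq),
            count_offset_h=float(row.count_offset_h),
        )
        for row in frame.itertuples()
    ]


def write_biodist_csv(samples: list[BiodistSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "mouse_id": [s.mouse_id for s in samples],
            "organ": [s.organ for s in samples],
            "time_h": [s.time_h for s in samples],
            "mass_g": [s.mass_g for s in samples],
            "counts_cpm": [s.counts_cpm for s in samples],
            "counter_eff_cpm_per_MBq": [s.counter_eff_cpm_per_mbq for s in samples],
            "injected_MBq": [s.injected_mbq for s in samples],
            "count_offset_h": [s.count_offset_h for s in samples],
        }
    ).to_csv(path, index=False)


def read_growth_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    needed = {"mouse_id", "group", "day"}
    if not needed <= set(frame.columns):
        raise ValueError(f"{path}: growth CSV needs columns {sorted(needed)}")
    if "volume_mm3" not in frame.columns and not {
        "length_mm",
        "width_mm",
    } <= set(frame.columns):
        raise ValueError(f"{path}: needs volume_mm3 or length_mm+width_mm")
    return frame


def read_lindmo_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    needed = {"cell_count", "bound_counts", "supernatant_counts"}
    if not needed <= set(frame.columns):
        raise ValueError(f"{path}: Lindmo CSV needs columns {sorted(needed)}")
    return frame


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def _check_numeric(frame: pd.DataFrame, col: str, label: str, issues: list[str],
                   minimum: float | None = None, strict: bool = False) -> None:
    vals = pd.to_numeric(frame[col], errors="coerce")
    bad = vals.isna()
    for idx in frame.index[bad]:
        issues.append(f"{label} row {idx}: column {col!r} is not numeric")
    if minimum is not None:
        if strict:
            viol = vals.le(minimum) & ~bad
        else:
            viol = vals.lt(minimum) & ~bad
        for idx in frame.index[viol]:
            issues.append(
                f"{label} row {idx}: column {col!r} = {vals[idx]} violates "
                f"{'>' if strict else '>='} {minimum}"
            )


def validate_inputs(
    biodist: str | Path | None = None,
    phantom: str | Path | None = None,
    nuclides: str | Path | None = None,
    lindmo: str | Path | None = None,
    growth: str | Path | None = None,
    nuclide_names: tuple[str, ...] = (),
) -> ValidationReport:
    """Schema-check every provided input; never raises past this boundary."""
    issues: list[str] = []
    if biodist is not None:
        try:
            frame = pd.read_csv(biodist)
            missing = [c for c in BIODIST_COLUMNS if c not in frame.columns]
            if missing:
                issues.append(f"biodist: missing columns {missing}")
            else:
                _check_numeric(frame, "mass_g", "biodist", issues, 0.0, strict=True)
                _check_numeric(frame, "counts_cpm", "biodist", issues, 0.0)
                _check_numeric(frame, "injected_MBq", "biodist", issues, 0.0, strict=True)
                _check_numeric(frame, "time_h", "biodist", issues, 0.0)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            issues.append(f"biodist: unreadable ({exc})")
    if phantom is not None:
        try:
            build_phantom(load_phantom_spec(phantom))
        except FileNotFoundError:
            issues.append(f"phantom: file not found: {phantom}")
        except Exception as exc:  # noqa: BLE001
            issues.append(f"phantom: {exc}")
    for name in nuclide_names:
        try:
            load_nuclide(name, nuclides)
        except Exception as exc:  # noqa: BLE001
            issues.append(f"nuclide {name!r}: {exc}")
    if lindmo is not None:
        try:
            frame = read_lindmo_csv(lindmo)
            _check_numeric(frame, "cell_count", "lindmo", issues, 0.0, strict=True)
            _check_numeric(frame, "bound_counts", "lindmo", issues, 0.0)
            _check_numeric(frame, "supernatant_counts", "lindmo", issues, 0.0)
        except Exception as exc:  # noqa: BLE001
            issues.append(f"lindmo: {exc}")
    if growth is not None:
        try:
            frame = read_growth_csv(growth)
            for mouse, sub in frame.groupby("mouse_id"):
                if np.any(np.diff(sub["day"].to_numpy(dtype=float)) <= 0):
                    issues.append(f"growth: mouse {mouse}: days not increasing")
        except Exception as exc:  # noqa: BLE001
            issues.append(f"growth: {exc}")
    return ValidationReport(issues=issues)


def _fit_organ(config: PipelineConfig, curve, organ: str) -> KineticFit:
    if organ in config.hybrid_organs:
        return fit_hybrid(curve, poly_degree=config.poly_degree)
    return fit_monoexp(curve)


def run_dosimetry(config: PipelineConfig) -> dict[str, DoseReport]:
    """Execute the full chain and write artifacts to ``config.out_dir``.

    Returns one DoseReport per therapy nuclide.  Any stage failure aborts
    with a stage-tagged error after flushing a FAILED marker file.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "config"
    try:
        source = load_nuclide(config.source_nuclide, config.nuclide_registry_path)
        targets = [
            load_nuclide(n, config.nuclide_registry_path)
            for n in config.therapy_nuclides
        ]

        stage = "read_biodist"
        samples = read_biodist_csv(config.biodist_path)

        stage = "phantom"
        phantom = build_phantom(load_phantom_spec(config.phantom_path))
        organ_names = phantom.region_names

        stage = "aggregate"
        organs_in_data = sorted({s.organ for s in samples})
        curves = {
            organ: aggregate_curve(
                samples,
                organ,
                nuclide=source,
                decay_correct_offset=config.decay_correct_offset,
                decay_corrected=config.decay_corrected_counts,
                unit="pia",
            )
            for organ in organs_in_data
        }

        stage = "fit"
        fits = {organ: _fit_organ(config, curve, organ) for organ, curve in curves.items()}

        reports: dict[str, DoseReport] = {}
        for target in targets:
            stage = f"extrapolate:{target.name}"
            target_fits = {
                organ: extrapolate_to_nuclide(fit, target)
                for organ, fit in fits.items()
            }

            stage = f"integrate:{target.name}"
            cums: dict[str, CumulatedActivity] = {}
            for organ, fit in target_fits.items():
                first_t = float(curves[organ].times_h[0])
                if config.integration == "full":
                    flat = first_t if organ not in config.hybrid_organs else None
                    cums[organ] = cumulated_activity(
                        fit, 0.0, math.inf, curve_unit="percent",
                        flat_back_from_h=flat,
                    )
                else:
                    cums[organ] = cumulated_activity(
                        fit, first_t, float(curves[organ].times_h[-1]),
                        curve_unit="percent",
                    )
            if config.blood_into and "blood" in cums and config.blood_into in cums:
                extra = cums.pop("blood")
                host = cums[config.blood_into]
                cums[config.blood_into] = CumulatedActivity(
                    organ=host.organ,
                    nuclide=host.nuclide,
                    value_s=host.value_s + extra.value_s,
                    t_lo_h=host.t_lo_h,
                    t_hi_h=host.t_hi_h,
                    method=host.method + " (+blood pool)",
                )

            stage = f"svalue:{target.name}"
            smat = svalue_matrix(
                phantom, target, n_particles=config.n_particles, seed=config.seed
            )
            s_lookup = {(r.source, r.target): r for r in smat}

            stage = f"dose:{target.name}"
            rows = []
            inj_bq = config.injected_mbq * 1e6
            for organ in organ_names:
                dose = 0.0
                for src in organ_names:
                    if src not in cums:
                        continue
                    dose += cums[src].value_s * inj_bq * s_lookup[(src, organ)].s_value
                self_cum = cums.get(organ)
                rows.append(
                    {
                        "organ": organ,
                        "cum_bq_s": (self_cum.value_s * inj_bq) if self_cum else 0.0,
                        "s_gy_per_bq_s": s_lookup[(organ, organ)].s_value,
                        "dose_gy": dose,
                        "dose_gy_sd": np.nan,
                        "dose_per_mbq": dose / config.injected_mbq,
                    }
                )
            reports[target.name] = DoseReport(
                nuclide=target.name,
                injected_mbq=config.injected_mbq,
                rows=pd.DataFrame(rows),
            )

        stage = "write"
        tidy_frames = []
        for name, rep in reports.items():
            ratios = tumor_to_organ_ratios(rep)
            merged = rep.rows.merge(
                ratios[["organ", "ratio"]].rename(columns={"ratio": "tumor_ratio"}),
                on="organ",
            )
            merged.insert(0, "nuclide", name)
            tidy_frames.append(merged)
        pd.concat(tidy_frames, ignore_index=True).to_csv(
            out_dir / "dose_report.csv", index=False
        )
        text, _ = render_dose_table(list(reports.values()))
        (out_dir / "dose_table.txt").write_text(text, encoding="utf-8")
        provenance = {
            "tool": "ritdose",
            "version": __version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "elapsed_s": round(time.time() - t_start, 3),
        }
        (out_dir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, default=str), encoding="utf-8"
        )
        return reports
    except StageError:
        raise
    except Exception as exc:
        try:
            (out_dir / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        except OSError:  # pragma: no cover - best effort marker
            pass
        raise StageError(stage, str(exc)) from exc
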