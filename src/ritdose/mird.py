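"""MIRD dose assembly: absorbed doses, per-MBq doses, tumor-to-organ ratios.

The MIRD formalism computes the absorbed dose to a target region as the
cumulated activity in each source region times the S-value coupling the
pair: D(target) = sum_sources A~(source) * S(source -> target).  This module
assembles those products into dose reports shaped like the study's dose
table, with tumor-to-organ ratios computed from unrounded doses and
displayed at two decimals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biodist import CumulatedActivity
from .svalue import SValueResult

__all__ = [
    "ORGAN_ORDER",
    "DoseReport",
    "absorbed_dose",
    "tumor_to_organ_ratios",
    "dose_uncertainty",
    "render_dose_table",
]

#: display order of the standard dose table rows
ORGAN_ORDER = (
    "tumor",
    "spleen",
    "kidneys",
    "liver",
    "heart",
    "lungs",
    "brain",
    "rest_of_body",
)


def absorbed_dose(
    cum: CumulatedActivity, s: SValueResult, injected_mbq: float
) -> tuple[float, float]:
    """Dose [Gy] and dose per injected MBq [Gy/MBq] for one organ.

    ``cum.value_s`` is Bq·s per Bq injected; the injected activity converts
    it to absolute Bq·s before multiplying by the S-value (Gy per Bq·s).
    """
    if cum.organ != s.target:
        raise ValueError(f"organ mismatch: cumulated {cum.organ!r} vs S {s.target!r}")
    if cum.nuclide is not None and cum.nuclide.name != s.nuclide:
        raise ValueError(
            f"nuclide mismatch: cumulated {cum.nuclide.name!r} vs S {s.nuclide!r}"
        )
    if injected_mbq <= 0:
        raise ValueError("injected activity must be > 0")
    cum_bq_s = cum.value_s * injected_mbq * 1e6
    dose_gy = cum_bq_s * s.s_value
    return dose_gy, dose_gy / injected_mbq


@dataclass
class DoseReport:
    """Per-organ doses for one nuclide and one injected activity.

    ``rows`` columns: organ, cum_bq_s, s_gy_per_bq_s, dose_gy, dose_gy_sd,
    dose_per_mbq.  Doses satisfy dose = cum * S row-wise when assembled from
    self-dose terms only; multi-source assembly stores the summed dose with
    cum/S of the self term for reference.
    """

    nuclide: str
    injected_mbq: float
    rows: pd.DataFrame

    @classmethod
    def from_doses(
        cls,
        nuclide: str,
        injected_mbq: float,
        doses_gy: dict[str, float],
        dose_sds_gy: dict[str, float] | None = None,
    ) -> "DoseReport":
        """Build a report directly from per-organ doses (e.g. published values)."""
        sds = dose_sds_gy or {}
        rows = pd.DataFrame(
            {
                "organ": list(doses_gy),
                "cum_bq_s": np.nan,
                "s_gy_per_bq_s": np.nan,
                "dose_gy": list(doses_gy.values()),
                "dose_gy_sd": [sds.get(o, np.nan) for o in doses_gy],
                "dose_per_mbq": [d / injected_mbq for d in doses_gy.values()],
            }
        )
        return cls(nuclide=nuclide, injected_mbq=injected_mbq, rows=rows)

    def dose(self, organ: str) -> float:
        sel = self.rows.loc[self.rows["organ"] == organ, "dose_gy"]
        if sel.empty:
            raise KeyError(f"no organ {organ!r} in report")
        return float(sel.iloc[0])


def tumor_to_organ_ratios(
    report: DoseReport, reference: str = "tumor"
) -> pd.DataFrame:
    """D_reference / D_organ for every organ, from unrounded doses.

    Returns columns ``organ``, ``ratio`` (raw) and ``ratio_display``
    (rounded to two decimals, as dose tables print them).  A zero organ dose
    yields a NaN ratio (undefined marker), never infinity.
    """
    ref_dose = report.dose(reference)
    if not ref_dose > 0:
        raise ValueError(f"reference organ {reference!r} has nonpositive dose")
    organs = report.rows["organ"].tolist()
    doses = report.rows["dose_gy"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        ratios = np.where(doses > 0, ref_dose / doses, np.nan)
    return pd.DataFrame(
        {
            "organ": organs,
            "ratio": ratios,
            "ratio_display": np.round(ratios, 2),
        }
    )


def dose_uncertainty(cum_rel_sd: float, s_rel_unc: float) -> float:
    """Relative dose uncertainty of the product, in quadrature."""
    if cum_rel_sd < 0 or s_rel_unc < 0:
        raise ValueError("relative uncertainties must be nonnegative")
    return float(np.hypot(cum_rel_sd, s_rel_unc))


def _ordered(rows: pd.DataFrame) -> pd.DataFrame:
    order = {name: i for i, name in enumerate(ORGAN_ORDER)}
    key = rows["organ"].map(lambda o: order.get(o, len(order)))
    return rows.iloc[np.argsort(key.to_numpy(), kind="stable")]


def render_dose_table(
    reports: list[DoseReport], reference: str = "tumor"
) -> tuple[str, pd.DataFrame]:
    """Deterministic text + tidy frame of doses and tumor-to-organ ratios.

    One dose column and one ratio column per nuclide, organs in the standard
    table order (tumor first).  The returned frame keeps raw unrounded
    values; only the text is rounded for display.
    """
    if not reports:
        raise ValueError("no reports to render")
    frames = []
    for rep in reports:
        rows = _ordered(rep.rows).copy()
        ratios = tumor_to_organ_ratios(rep, reference=reference)
        rows = rows.merge(ratios[["organ", "ratio"]], on="organ")
        rows.insert(0, "nuclide", rep.nuclide)
        frames.append(rows)
    tidy = pd.concat(frames, ignore_index=True)

    buf = io.StringIO()
    nuclides = [r.nuclide for r in reports]
    header = ["Organ"] + [f"Dose(Gy) {n}" for n in nuclides] + [
        f"D_{reference}/D_organ {n}" for n in nuclides
    ]
    buf.write("\t".join(header) + "\n")
    organs = _ordered(reports[0].rows)["organ"].tolist()
    for organ in organs:
        cells = [organ]
        for rep in reports:
            cells.append(f"{rep.dose(organ):.2f}")
        for rep in reports:
            ratio = tumor_to_organ_ratios(rep, reference=reference)
            val = ratio.loc[ratio["organ"] == organ, "ratio_display"].iloc[0]
            cells.append("-" if organ == reference else f"{val:.2f}")
        buf.write("\t".join(cells) + "\n")
    return buf.getvalue(), tidy
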