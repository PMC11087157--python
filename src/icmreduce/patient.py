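"""Worked-example arithmetic for patient ROI summary statistics.

Operates on printed aorta ROI statistics (mean +/- SD in HU) from paired
full-dose and reduced-dose contrast CT exams, reproducing the bookkeeping a
physicist does when auditing a contrast-reduction protocol:

* ``percent_difference`` — how closely a CNR-matched low-keV reduced-dose
  image reproduces the full-dose enhancement.  Reporting convention: the
  reduced-dose, lower-keV (CNR-matched) measurement is the denominator.
* ``percent_drop`` — enhancement lost at matched keV when the contrast
  volume is cut; the full-dose scan is the denominator.
* ``case_cnr`` — same CNR definition as the phantom pipeline, from a
  muscle background mean/SD.

Rounding mirrors standard reporting: differences to one decimal, drops to
the nearest integer; volume reductions are shown both ways.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import ConfigError, DegenerateInputError
from .measure import ROIStats, compute_cnr


@dataclass(frozen=True)
class CaseMeasurement:
    """One aorta ROI summary from a patient scan."""

    label: str  # dose level + keV, e.g. "full_70keV"
    mean_hu: float
    sd_hu: float
    background_mean_hu: float | None = None
    background_sd_hu: float | None = None

    def __post_init__(self):
        if self.sd_hu < 0:
            raise ConfigError("sd_hu must be >= 0")


def percent_difference(reference: CaseMeasurement, other: CaseMeasurement) -> float:
    """Unsigned percent difference of mean HU relative to ``reference``.

    By reporting convention the reference is the reduced-dose, CNR-matched
    low-keV measurement.
    """
    if reference.mean_hu == 0:
        raise DegenerateInputError("reference mean HU is zero")
    return 100.0 * abs(other.mean_hu - reference.mean_hu) / abs(reference.mean_hu)


def percent_drop(baseline: CaseMeasurement, followup: CaseMeasurement) -> float:
    """Percent decrease of mean HU from a full-dose baseline to a follow-up."""
    if baseline.mean_hu <= 0:
        raise DegenerateInputError("baseline mean HU must be positive")
    return 100.0 * (baseline.mean_hu - followup.mean_hu) / baseline.mean_hu


def volume_reduction_pct(full_ml: float, reduced_ml: float) -> float:
    """Percent reduction of administered contrast volume."""
    if full_ml <= 0:
        raise ConfigError("full contrast volume must be positive")
    return 100.0 * (full_ml - reduced_ml) / full_ml


def case_cnr(m: CaseMeasurement) -> float:
    """CNR of the vessel against the muscle background (same definition as phantoms)."""
    for fld in ("background_mean_hu", "background_sd_hu"):
        if getattr(m, fld) is None:
            raise ConfigError(f"case {m.label!r} is missing field {fld!r}")
    return compute_cnr(
        ROIStats(m.mean_hu, m.sd_hu, 1, m.label),
        ROIStats(m.background_mean_hu, m.background_sd_hu, 1, "background"),
    )


def load_cases(path=None) -> dict:
    """Load a patient-case JSON; defaults to the packaged two-patient example."""
    if path is None:
        ref = resources.files("icmreduce.data") / "patients_example.json"
        data = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            data = json.loads(fh.read())
    return data


def _case(d: dict, label: str) -> CaseMeasurement:
    return CaseMeasurement(
        label=label,
        mean_hu=float(d["mean_hu"]),
        sd_hu=float(d["sd_hu"]),
        background_mean_hu=d.get("background_mean_hu"),
        background_sd_hu=d.get("background_sd_hu"),
    )


def patient_report(cases: dict) -> pd.DataFrame:
    """Tidy report of the per-patient arithmetic.

    Expects the schema of the packaged example: per patient, a
    ``full_70keV`` scan, a ``reduced_70keV`` follow-up, and a CNR-matched
    ``reduced_lowkeV`` follow-up; optionally ``printed_cnr`` values, which
    are echoed for context (their background statistics are not published,
    so they are not recomputable).  Both orderings of the percent
    difference are exposed; the ``reference`` column names the denominator.
    """
    rows = []
    for patient, scans in cases.items():
        if patient == "contrast_volume_ml":
            continue
        full = _case(scans["full_70keV"], "full_70keV")
        red70 = _case(scans["reduced_70keV"], "reduced_70keV")
        redlow = _case(scans["reduced_lowkeV"], scans["reduced_lowkeV"].get("label", "reduced_lowkeV"))
        rows.append(
            {
                "patient": patient,
                "metric": "hu_difference_pct",
                "reference": redlow.label,
                "value": round(percent_difference(redlow, full), 1),
            }
        )
        rows.append(
            {
                "patient": patient,
                "metric": "hu_difference_pct_alt_reference",
                "reference": full.label,
                "value": round(percent_difference(full, redlow), 1),
            }
        )
        rows.append(
            {
                "patient": patient,
                "metric": "hu_drop_at_70kev_pct",
                "reference": full.label,
                "value": round(percent_drop(full, red70)),
            }
        )
        for key, case in (("full_70keV", full), ("reduced_70keV", red70), ("reduced_lowkeV", redlow)):
            printed = scans[key].get("printed_cnr")
            if printed is not None:
                rows.append(
                    {
                        "patient": patient,
                        "metric": f"published_cnr_{case.label}",
                        "reference": "psoas (statistics unpublished; shown for context)",
                        "value": printed,
                    }
                )
    vol = cases.get("contrast_volume_ml")
    if vol:
        pct = volume_reduction_pct(float(vol["full"]), float(vol["reduced"]))
        rows.append(
            {"patient": "all", "metric": "contrast_volume_reduction_pct",
             "reference": "full volume", "value": round(pct)}
        )
        rows.append(
            {"patient": "all", "metric": "contrast_volume_reduction_pct_1dp",
             "reference": "full volume", "value": round(pct, 1)}
        )
    return pd.DataFrame(rows, columns=["patient", "metric", "reference", "value"])
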