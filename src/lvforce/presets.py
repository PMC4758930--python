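"""Cohort presets for the synthetic LV phantom.

The numeric preset values (force-ratio, mean transverse-force, end-diastolic
volume and sphericity-index distributions per group) are taken from published
group statistics for healthy subjects and dilated-cardiomyopathy (DCM)
patients measured with 4D flow MRI.  They parameterize the simulation — the
generator draws per-subject targets from these distributions and builds a
velocity field that reproduces them — and are not re-derived by this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CohortPreset", "PRESETS"]


@dataclass(frozen=True)
class CohortPreset:
    """Per-subject parameter distributions, (mean, SD) unless noted."""

    name: str
    ratio_e: tuple[float, float]  # E-wave SAx-max/LAx-max force ratio
    ratio_a: tuple[float, float]  # A-wave ratio
    mean_sax_e: tuple[float, float]  # time-averaged SAx-plane force, E (N)
    mean_sax_a: tuple[float, float]  # same, A-wave (N)
    edv_ml: tuple[float, float]  # end-diastolic volume (mL)
    si: tuple[float, float]  # sphericity index (diameter / length)
    ef: float  # ejection fraction (volume waveform endpoint)
    si_ratio_corr: float = 0.3  # within-group SI ~ ratio_e coupling
    e_jet_speed: float = 0.8  # transmitral E jet peak (m/s)
    a_jet_speed: float = 0.5
    aov_jet_speed: float = 1.1  # systolic LVOT jet peak (m/s)
    syst_force: float = 0.18  # systolic long-axis peak force (N), not graded


PRESETS: dict[str, CohortPreset] = {
    "healthy": CohortPreset(
        name="healthy",
        ratio_e=(0.23, 0.12),
        ratio_a=(0.26, 0.09),
        mean_sax_e=(0.032, 0.007),
        mean_sax_a=(0.034, 0.012),
        edv_ml=(137.0, 15.0),
        si=(0.56, 0.06),
        ef=0.61,
        e_jet_speed=0.8,
        a_jet_speed=0.5,
        aov_jet_speed=1.1,
        syst_force=0.18,
    ),
    "dcm": CohortPreset(
        name="dcm",
        ratio_e=(0.53, 0.15),
        ratio_a=(0.44, 0.21),
        mean_sax_e=(0.045, 0.011),
        mean_sax_a=(0.032, 0.014),
        edv_ml=(177.0, 33.0),
        si=(0.75, 0.12),
        ef=0.41,
        e_jet_speed=0.6,
        a_jet_speed=0.5,
        aov_jet_speed=0.8,
        syst_force=0.12,
    ),
    # DCM subgroup with normal diastolic function; volumes/shape as DCM
    "dcm_normal_diastolic": CohortPreset(
        name="dcm_normal_diastolic",
        ratio_e=(0.58, 0.11),
        ratio_a=(0.37, 0.1479),
        mean_sax_e=(0.045, 0.011),
        mean_sax_a=(0.032, 0.014),
        edv_ml=(177.0, 33.0),
        si=(0.75, 0.12),
        ef=0.41,
        e_jet_speed=0.7,
        a_jet_speed=0.5,
        aov_jet_speed=0.9,
        syst_force=0.12,
    ),
}
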