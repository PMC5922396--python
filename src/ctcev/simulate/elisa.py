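"""Synthetic ELISA plates generated from a known 4-parameter logistic
calibration curve, for round-trip validation of the quantification step."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ctcev.biomarkers import ElisaPlate


def four_pl(x, a, d, c, b):
    """4-parameter logistic: a = zero-dose response, d = saturation,
    c = inflection concentration, b = slope."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass
class ElisaSimParams:
    """Plate generator parameters.

    Defaults mimic an M65-style kit: 7 standards on a 2-fold dilution series
    (62.5 - 4000 U/L), low/high QC near 150 and 1500 U/L, blank absorbance
    0.05, absorbance noise sd 0.005 (optical density units).
    """

    curve: tuple = (0.04, 3.2, 700.0, 1.1)  # (a, d, c, b)
    standards: tuple = (62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0)
    blank: float = 0.05
    qc_low_conc: float = 150.0
    qc_high_conc: float = 1500.0
    qc_tolerance: float = 0.30  # declared QC range = conc * (1 -/+ tolerance)
    sample_concentrations: dict = field(
        default_factory=lambda: {"s1": 120.0, "s2": 400.0, "s3": 900.0, "s4": 2500.0}
    )
    noise_sd: float = 0.005
    seed: int = 0


def generate_elisa_plate(params: ElisaSimParams) -> tuple[ElisaPlate, dict]:
    """Generate one plate; returns ``(plate, true_concentrations)``.

    Standards are single wells at their defined concentrations; QC wells and
    samples are technical duplicates.  Absorbances are the 4PL response plus
    the blank plus Gaussian noise; ``noise_sd = 0`` gives an exact plate.
    """
    rng = np.random.default_rng(params.seed)
    a, d, c, b = params.curve

    def absorbance(conc, size=None):
        y = four_pl(conc, a, d, c, b) + params.blank
        if params.noise_sd > 0:
            y = y + rng.normal(0.0, params.noise_sd, size=size)
        return y

    standards = [(conc, float(absorbance(conc))) for conc in params.standards]
    qc_low = (
        tuple(float(v) for v in np.atleast_1d(absorbance(params.qc_low_conc, size=2))[:2])
        if params.noise_sd > 0
        else (float(absorbance(params.qc_low_conc)),) * 2,
        (
            params.qc_low_conc * (1 - params.qc_tolerance),
            params.qc_low_conc * (1 + params.qc_tolerance),
        ),
    )
    qc_high = (
        tuple(float(v) for v in np.atleast_1d(absorbance(params.qc_high_conc, size=2))[:2])
        if params.noise_sd > 0
        else (float(absorbance(params.qc_high_conc)),) * 2,
        (
            params.qc_high_conc * (1 - params.qc_tolerance),
            params.qc_high_conc * (1 + params.qc_tolerance),
        ),
    )
    samples = {}
    for name, conc in params.sample_concentrations.items():
        if params.noise_sd > 0:
            pair = absorbance(conc, size=2)
            samples[name] = (float(pair[0]), float(pair[1]))
        else:
            v = float(absorbance(conc))
            samples[name] = (v, v)
    plate = ElisaPlate(
        blank=params.blank,
        standards=standards,
        samples=samples,
        qc_low=qc_low,
        qc_high=qc_high,
    )
    return plate, dict(params.sample_concentrations)
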