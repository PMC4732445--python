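"""Blood-gas corrections and derived analytes.

Point-of-care analysers report pH, pCO2 and pO2 at the electrode temperature
(conventionally 37 degC).  A cold-stunned sea turtle is admitted at a cloacal
temperature of roughly 5-15 degC, so raw analyser values must be corrected to
body temperature before they are interpreted or scored, and bicarbonate is
then derived from the corrected pH/pCO2 pair via Henderson-Hasselbalch:

    HCO3- = alphaCO2(T) * pCO2 * 10**(pH - pK(T))

The numerical coefficients involved -- the temperature-correction slopes, the
CO2 solubility ``alphaCO2``, the apparent ``pK`` and the pH slope used to
standardise ionized calcium -- are species- and method-dependent.  They are
therefore data, not code: each named :class:`CorrectionCoefficients` set is
loaded from a config document, and every set carries a provenance label.  Two
sets ship with the package:

``human-default``
    Standard human blood-gas constants: alphaCO2 = 0.0307 mmol/l/mmHg,
    pK' = 6.1, linear pH correction (-0.0147 /degC) and log-linear pCO2/pO2
    corrections.  Usable out of the box but not species-specific.

``kemps-ridley``
    A placeholder whose numeric coefficients must be transcribed by the user
    from the species literature.  Using it before the coefficients are filled
    in raises :class:`~coldstun_mpi.errors.ConfigurationError` naming the
    missing function -- never a silent fallback to human constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError

PH_WINDOW = (6.0, 9.0)
DEFAULT_COEFF_SET = "human-default"


@dataclass(frozen=True)
class CorrectionCoefficients:
    """A named, provenance-labelled set of blood-gas correction coefficients.

    Temperature corrections (``dT`` = body - analyser temperature):

    * pH:   additive, ``pH + ph_slope_per_C * dT``
    * pCO2: log-linear, ``pCO2 * 10**(pco2_log10_per_C * dT)``
    * pO2:  log-linear, ``pO2 * 10**(po2_log10_per_C * dT)``

    ``alpha_co2_poly`` is ``(a0, a1, a2)`` in mmol/l/mmHg evaluated as a
    quadratic in ``T - alpha_t_ref``; ``pk`` is linear in temperature and,
    optionally, in ``7.4 - pH``.  Ionized calcium is standardised to a target
    pH multiplicatively: ``iCa * 10**(ica_log10_slope * (pH_meas - pH_tgt))``.

    Any coefficient may be ``None`` (unconfigured); the operation that needs
    it raises a :class:`ConfigurationError` naming it.
    """

    name: str
    provenance: str
    ph_slope_per_C: Optional[float] = None
    pco2_log10_per_C: Optional[float] = None
    po2_log10_per_C: Optional[float] = None
    alpha_co2_poly: Optional[tuple[float, float, float]] = None
    alpha_t_ref: float = 37.0
    pk_const: Optional[float] = None
    pk_t_slope: float = 0.0
    pk_ph_slope: float = 0.0
    pk_t_ref: float = 37.0
    ica_log10_slope: Optional[float] = None
    ica_ph_ref: float = 7.4
    temp_range: tuple[float, float] = (0.0, 40.0)

    def _require(self, attr: str, label: str) -> float:
        value = getattr(self, attr)
        if value is None:
            raise ConfigurationError(
                f"coefficient set {self.name!r} does not configure {label} "
                f"(field {attr!r}); supply it in the coefficient config"
            )
        return value

    def check_temp(self, temp: float) -> None:
        lo, hi = self.temp_range
        if not (lo <= temp <= hi):
            raise DomainError(
                f"temperature {temp} degC outside supported range "
                f"[{lo}, {hi}] of coefficient set {self.name!r}"
            )

    def alpha_co2(self, temp: float) -> float:
        """CO2 solubility in mmol/l/mmHg at ``temp`` degC."""
        self.check_temp(temp)
        poly = self._require("alpha_co2_poly", "the CO2 solubility alphaCO2(T)")
        a0, a1, a2 = poly
        dt = temp - self.alpha_t_ref
        return a0 + a1 * dt + a2 * dt * dt

    def pk(self, temp: float, ph: Optional[float] = None) -> float:
        """Apparent pK at ``temp`` degC (and optionally at ``ph``)."""
        self.check_temp(temp)
        const = self._require("pk_const", "the apparent pK(T)")
        value = const + self.pk_t_slope * (temp - self.pk_t_ref)
        if ph is not None:
            value += self.pk_ph_slope * (7.4 - ph)
        return value

    def validate(self) -> None:
        """Check physical invariants over the supported temperature range.

        alphaCO2 must be strictly positive and pK must stay within
        [5.5, 7.0]; sets with unconfigured coefficients skip the checks that
        do not apply (they fail later, loudly, if actually used).
        """
        grid = np.linspace(self.temp_range[0], self.temp_range[1], 41)
        if self.alpha_co2_poly is not None:
            alphas = [self.alpha_co2(float(t)) for t in grid]
            if min(alphas) <= 0:
                raise ConfigurationError(
                    f"coefficient set {self.name!r}: alphaCO2 must be > 0 over "
                    f"{self.temp_range}; minimum was {min(alphas):.5g}"
                )
        if self.pk_const is not None:
            pks = [self.pk(float(t)) for t in grid]
            if min(pks) < 5.5 or max(pks) > 7.0:
                raise ConfigurationError(
                    f"coefficient set {self.name!r}: pK must lie in [5.5, 7.0] "
                    f"over {self.temp_range}; range was "
                    f"[{min(pks):.4g}, {max(pks):.4g}]"
                )


def _coeffs_from_mapping(name: str, doc: dict) -> CorrectionCoefficients:
    tc = doc.get("temperature_correction") or {}
    alpha = doc.get("alpha_co2")
    pk = doc.get("pk")
    ica = doc.get("ionized_calcium") or {}
    alpha_poly = None
    alpha_t_ref = 37.0
    if alpha is not None and alpha.get("a0") is not None:
        alpha_poly = (
            float(alpha["a0"]),
            float(alpha.get("a1", 0.0)),
            float(alpha.get("a2", 0.0)),
        )
        alpha_t_ref = float(alpha.get("t_ref", 37.0))
    coeffs = CorrectionCoefficients(
        name=name,
        provenance=str(doc.get("provenance", "unspecified")),
        ph_slope_per_C=tc.get("ph_slope_per_C"),
        pco2_log10_per_C=tc.get("pco2_log10_per_C"),
        po2_log10_per_C=tc.get("po2_log10_per_C"),
        alpha_co2_poly=alpha_poly,
        alpha_t_ref=alpha_t_ref,
        pk_const=None if pk is None else pk.get("const"),
        pk_t_slope=0.0 if pk is None else float(pk.get("t_slope", 0.0)),
        pk_ph_slope=0.0 if pk is None else float(pk.get("ph_slope", 0.0)),
        pk_t_ref=37.0 if pk is None else float(pk.get("t_ref", 37.0)),
        ica_log10_slope=ica.get("log10_slope"),
        ica_ph_ref=float(ica.get("ph_ref", 7.4)),
        temp_range=tuple(doc.get("temp_range", (0.0, 40.0))),  # type: ignore[arg-type]
    )
    coeffs.validate()
    return coeffs


def load_coefficients(
    name: str = DEFAULT_COEFF_SET, path: str | Path | None = None
) -> CorrectionCoefficients:
    """Load a named coefficient set from a YAML/JSON config document.

    With ``path=None`` the packaged config (bundling ``human-default`` and the
    ``kemps-ridley`` placeholder) is used.
    """
    if path is None:
        text = (
            resources.files("coldstun_mpi.data")
            .joinpath("coefficient_sets.yaml")
            .read_text()
        )
        doc = yaml.safe_load(text)
    else:
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    sets = doc.get("sets", doc)
    if name not in sets:
        raise ConfigurationError(
            f"no coefficient set named {name!r}; available: {sorted(sets)}"
        )
    return _coeffs_from_mapping(name, sets[name])


def temperature_correct(
    raw_ph: float,
    raw_pco2: float,
    raw_po2: float,
    analyser_temp: float,
    body_temp: float,
    coeffs: CorrectionCoefficients,
) -> tuple[float, float, float]:
    """Correct a raw (pH, pCO2, pO2) triple from analyser to body temperature.

    The correction is the identity when the two temperatures coincide, and is
    exactly invertible by swapping the temperatures.
    """
    coeffs.check_temp(analyser_temp)
    coeffs.check_temp(body_temp)
    if not (PH_WINDOW[0] <= raw_ph <= PH_WINDOW[1]):
        raise DomainError(f"pH {raw_ph} outside sanity window {PH_WINDOW}")
    if raw_pco2 < 0 or raw_po2 < 0:
        raise DomainError("partial pressures must be >= 0 mmHg")
    dt = body_temp - analyser_temp
    ph_slope = coeffs._require("ph_slope_per_C", "the pH temperature correction")
    k_pco2 = coeffs._require("pco2_log10_per_C", "the pCO2 temperature correction")
    k_po2 = coeffs._require("po2_log10_per_C", "the pO2 temperature correction")
    return (
        raw_ph + ph_slope * dt,
        raw_pco2 * 10.0 ** (k_pco2 * dt),
        raw_po2 * 10.0 ** (k_po2 * dt),
    )


def calc_bicarbonate(
    ph: float,
    pco2: float,
    coeffs: CorrectionCoefficients,
    body_temp: float,
) -> float:
    """Henderson-Hasselbalch bicarbonate (mmol/l) from corrected pH and pCO2."""
    if pco2 < 0:
        raise DomainError(f"pCO2 must be >= 0 mmHg, got {pco2}")
    if not (PH_WINDOW[0] <= ph <= PH_WINDOW[1]):
        raise DomainError(f"pH {ph} outside sanity window {PH_WINDOW}")
    alpha = coeffs.alpha_co2(body_temp)
    pk = coeffs.pk(body_temp, ph)
    return alpha * pco2 * 10.0 ** (ph - pk)


def calc_anion_gap(
    sodium: float,
    potassium: float,
    chloride: float,
    bicarbonate: float,
    include_potassium: bool = True,
) -> float:
    """Anion gap in mmol/l: (Na [+ K]) - (Cl + HCO3).

    Potassium is included by default, matching common point-of-care analyser
    behaviour; pass ``include_potassium=False`` for the three-ion form.
    """
    for label, v in (
        ("sodium", sodium),
        ("potassium", potassium),
        ("chloride", chloride),
        ("bicarbonate", bicarbonate),
    ):
        if v < 0:
            raise DomainError(f"{label} must be >= 0 mmol/l, got {v}")
    cations = sodium + (potassium if include_potassium else 0.0)
    return cations - (chloride + bicarbonate)


def correct_ionized_calcium(
    ica_measured: float,
    ph_measured: float,
    ph_target: float,
    coeffs: CorrectionCoefficients,
) -> float:
    """Standardise ionized calcium (mmol/l) from measured pH to a target pH.

    Multiplicative form ``iCa * 10**(s * (pH_measured - pH_target))``; the
    identity when measured and target pH coincide.
    """
    if ica_measured < 0:
        raise DomainError(f"ionized calcium must be >= 0 mmol/l, got {ica_measured}")
    slope = coeffs._require("ica_log10_slope", "the ionized-calcium pH slope")
    corrected = ica_measured * 10.0 ** (slope * (ph_measured - ph_target))
    if corrected < 0:  # unreachable with the multiplicative form; guards config swaps
        raise DomainError("corrected ionized calcium is negative; check coefficients")
    return corrected
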