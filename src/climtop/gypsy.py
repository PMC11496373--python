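"""Species-specific top-height (site-index) equations and their inversion.

The Growth and Yield Projection System (GYPSY) expresses top height ``HT``
of a stand as a function of total age ``totage`` and site index ``SI``
(top height at a reference total age of 50 years).  Both supported species
use the same sigmoid-ratio form

    HT(SI, totage) = SI * (1 + exp(u(50))) / (1 + exp(u(totage)))

where the exponent ``u`` contains an age term, a site-index term and two
species constants.  The two species differ in the shape of the age and SI
terms:

* white spruce:   age term ``sqrt(ln(1 + totage**2))``, SI term ``ln(SI)**2``
* lodgepole pine: age term ``sqrt(ln(1 + totage))``,    SI term ``ln(SI)``

The fourth constant multiplies ``sqrt(50)`` in both numerator and
denominator and therefore only shifts the exponent; it is kept for
compatibility with the published four-constant parameterisation.

At ``totage = reference_age = 50`` numerator and denominator coincide, so
``HT(SI, 50) == SI`` exactly for any valid constants — the defining
identity of a site-index curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "DomainError",
    "InversionError",
    "SpeciesParams",
    "SPECIES_CODES",
    "evaluate_top_height",
    "invert_site_index",
    "annual_increment",
    "load_species_params",
    "default_species_params",
]

SPECIES_CODES = ("white_spruce", "lodgepole_pine")

#: Inversion bracket for site index (m).  Mapped site indices in boreal
#: plantations are well below 30 m; the bracket is generous but finite.
SI_BRACKET = (0.05, 80.0)

_REFERENCE_AGE = 50


class DomainError(ValueError):
    """An argument is outside the domain of the height equations."""


class InversionError(ValueError):
    """Site-index inversion failed (height not representable)."""


def _exponent(species_code: str, constants: tuple[float, ...],
              si, totage):
    """Exponent u(totage) of the height equation for one species form."""
    c1, c2, c3, c4 = constants
    si = np.asarray(si, dtype=float)
    totage = np.asarray(totage, dtype=float)
    if species_code == "white_spruce":
        age_term = np.sqrt(np.log1p(totage ** 2))
        si_term = np.log(si) ** 2
    else:  # lodgepole_pine
        age_term = np.sqrt(np.log1p(totage))
        si_term = np.log(si)
    return c1 + c2 * age_term + c3 * si_term + c4 * math.sqrt(_REFERENCE_AGE)


@dataclass(frozen=True)
class SpeciesParams:
    """Constants of one species' top-height equation.

    Parameters
    ----------
    species_code
        ``"white_spruce"`` or ``"lodgepole_pine"``; selects the equation form.
    constants
        The four dimensionless constants (b1..b4 for spruce, f1..f4 for pine).
    common_age
        Trial common age in years (16 for white spruce, 32 for lodgepole
        pine): the age to which provenance-trial heights are standardised.
    reference_age
        Age at which top height equals site index; fixed at 50 years.
    """

    species_code: str
    constants: tuple[float, float, float, float]
    common_age: int
    reference_age: int = _REFERENCE_AGE

    def __post_init__(self):
        if self.species_code not in SPECIES_CODES:
            raise DomainError(f"unknown species_code {self.species_code!r}")
        if len(self.constants) != 4 or not all(
                math.isfinite(c) for c in self.constants):
            raise DomainError("constants must be four finite numbers")
        if self.common_age <= 0:
            raise DomainError("common_age must be positive")
        if self.reference_age != _REFERENCE_AGE:
            raise DomainError("reference_age is fixed at 50")
        self._validate_monotone()

    def _validate_monotone(self):
        """Reject constants whose curve is not strictly increasing.

        Checked numerically: HT must increase strictly in totage over
        [1, 80] for site indices across the inversion bracket, and strictly
        in SI at every age (the latter guarantees a unique root for
        inversion).
        """
        ages = np.arange(1.0, 81.0)
        si_grid = np.concatenate([[SI_BRACKET[0]],
                                  np.geomspace(0.1, SI_BRACKET[1], 60)])
        for si in si_grid:
            h = evaluate_top_height(self, float(si), ages)
            if not np.all(np.diff(h) > 0):
                raise DomainError(
                    f"constants yield non-increasing height in age at SI={si:g}")
        for a in ages:
            h = evaluate_top_height(self, si_grid, float(a))
            if not np.all(np.diff(h) > 0):
                raise DomainError(
                    f"constants yield non-increasing height in SI at age={a:g}")


def evaluate_top_height(params: SpeciesParams, si, totage):
    """Top height (m) at total age ``totage`` on the curve with index ``si``.

    Accepts scalars or numpy arrays (broadcast); returns a float for
    scalar input.

    Raises
    ------
    DomainError
        If ``si <= 0`` or ``totage < 1`` (the result would be non-finite
        or outside the validated domain).
    """
    si_arr = np.asarray(si, dtype=float)
    age_arr = np.asarray(totage, dtype=float)
    if np.any(si_arr <= 0):
        raise DomainError(f"si must be > 0, got {si!r}")
    if np.any(age_arr < 1):
        raise DomainError(f"totage must be >= 1, got {totage!r}")
    num = 1.0 + np.exp(_exponent(params.species_code, params.constants,
                                 si_arr, params.reference_age))
    den = 1.0 + np.exp(_exponent(params.species_code, params.constants,
                                 si_arr, age_arr))
    ht = si_arr * num / den
    if not np.all(np.isfinite(ht)):
        raise DomainError("non-finite top height; check si/totage")
    if ht.ndim == 0:
        return float(ht)
    return ht


def invert_site_index(params: SpeciesParams, height: float,
                      totage: float) -> float:
    """Solve HT(si, totage) = height for the site index ``si``.

    Uses Brent's method on the bracket [0.05, 80] m; the root is unique
    because monotonicity of HT in si is validated when the parameters are
    loaded.

    Raises
    ------
    DomainError
        If ``height <= 0`` or ``totage < 1``.
    InversionError
        If the height is outside the range representable within the
        bracket ("height outside representable range").
    """
    if height <= 0:
        raise DomainError(f"height must be > 0, got {height!r}")
    if totage < 1:
        raise DomainError(f"totage must be >= 1, got {totage!r}")
    lo, hi = SI_BRACKET

    def f(si):
        return evaluate_top_height(params, si, totage) - height

    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise InversionError(
            f"height outside representable range: height={height:g} m at "
            f"totage={totage:g} (bracket [{lo}, {hi}] m)")
    return float(brentq(f, lo, hi, xtol=1e-10))


def annual_increment(params: SpeciesParams, si: float, age: int) -> float:
    """Height increment HT(si, age) - HT(si, age-1); strictly positive.

    Raises
    ------
    DomainError
        If ``age < 2``.
    """
    if age < 2:
        raise DomainError(f"age must be >= 2, got {age!r}")
    return (evaluate_top_height(params, si, age)
            - evaluate_top_height(params, si, age - 1))


# ---------------------------------------------------------------------------
# Parameter-file handling

_CONSTANT_KEYS = {
    "white_spruce": ("b1", "b2", "b3", "b4"),
    "lodgepole_pine": ("f1", "f2", "f3", "f4"),
}

_DEFAULT_PARAMS_FILE = Path(__file__).parent / "data" / "species_params_synthetic.yaml"


def load_species_params(path: str | Path,
                        species_code: str | None = None):
    """Load species parameters from a YAML key-value file.

    The file maps species codes to blocks with the four constants (``b1..b4``
    or ``f1..f4``) and ``common_age``.  Returns a single
    :class:`SpeciesParams` when ``species_code`` is given, else a dict of
    all species in the file.  Schema violations raise :class:`DomainError`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DomainError(f"malformed species parameter file: {path}")
    out = {}
    for code, block in raw.items():
        if code not in SPECIES_CODES:
            raise DomainError(f"unknown species_code {code!r} in {path}")
        keys = _CONSTANT_KEYS[code]
        try:
            constants = tuple(float(block[k]) for k in keys)
            common_age = int(block["common_age"])
        except (KeyError, TypeError, ValueError) as exc:
            raise DomainError(
                f"species block {code!r} must define {keys} and common_age"
            ) from exc
        out[code] = SpeciesParams(code, constants, common_age)
    if species_code is not None:
        if species_code not in out:
            raise DomainError(f"{species_code!r} not present in {path}")
        return out[species_code]
    return out


def default_species_params(species_code: str | None = None):
    """Parameters from the bundled synthetic calibration file.

    The published constants for the Alberta fits are not reproduced here;
    the shipped values are a synthetic calibration that satisfies every
    structural requirement of the equations (strict monotonicity in age
    and site index, HT(50) = SI) and gives realistic boreal-conifer curve
    shapes.  Analyses of real trial data should supply the regionally
    fitted constants via :func:`load_species_params`.
    """
    return load_species_params(_DEFAULT_PARAMS_FILE, species_code)
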