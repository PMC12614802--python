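"""Runtime configuration for the feature extractor.

Every geometric threshold that enters a feature definition lives here so
that alternative parameterizations (other radii tables, other hydropathy
scales, wider dispersion shells) are drop-in replacements.  Distances are
in Angstrom, angles in degrees, solvation parameters in kcal/mol/A^2.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

from . import _chem


@dataclass
class HBondConfig:
    """Geometric hydrogen-bond criteria and the linear score ramp.

    A donor-acceptor pair at ``d_ideal``/180 deg scores 1.0; the score
    falls linearly to 0 at ``d_max`` and at ``alpha_min``.
    """

    d_max: float = 3.5
    d_ideal: float = 2.6
    alpha_min: float = 100.0
    alpha_ideal: float = 180.0


@dataclass
class AsaConfig:
    probe: float = 1.4
    n_points: int = 256
    min_points: int = 32


@dataclass
class ContactConfig:
    """Distance bands for non-bonded pair classification.

    Bands are keyed to the vdW radius sum ``R = r_i + r_j``:
    repulsive d < R, van der Waals R <= d <= R + vdw_band,
    London dispersion R + vdw_band < d <= R + london_band.

    ``min_bonded_path`` is the minimum number of covalent bonds between
    two atoms for their distance to count as a non-covalent contact.
    The default of 5 excludes 1-2/1-3 pairs (pure bond geometry) and the
    1-4/1-5 separations fixed by torsions, so ideal covalent geometry
    registers zero repulsive clashes.
    """

    vdw_band: float = 0.7
    london_band: float = 3.0
    hydrophobic_cutoff: float = 4.5
    burial_rasa: float = 0.20
    min_bonded_path: int = 5


@dataclass
class FeatureConfig:
    vdw_radii: Mapping[str, float] = field(
        default_factory=lambda: dict(_chem.VDW_RADII))
    default_vdw_radius: float = _chem.DEFAULT_VDW_RADIUS
    covalent_radii: Mapping[str, float] = field(
        default_factory=lambda: dict(_chem.COVALENT_RADII))
    covalent_tolerance: float = 0.45
    hbond: HBondConfig = field(default_factory=HBondConfig)
    asa: AsaConfig = field(default_factory=AsaConfig)
    contacts: ContactConfig = field(default_factory=ContactConfig)
    hydropathy: Mapping[str, float] = field(
        default_factory=lambda: dict(_chem.KYTE_DOOLITTLE))
    max_asa: Mapping[str, float] = field(
        default_factory=lambda: dict(_chem.MAX_ASA))
    solvation_params: Mapping[str, float] = field(
        default_factory=lambda: dict(_chem.SOLVATION_PARAMS))
    alphabet: str = _chem.ALPHABET
    cpaasc_classes: Mapping[str, frozenset] = field(
        default_factory=lambda: {k: frozenset(v)
                                 for k, v in _chem.CPAASC_CLASSES.items()})
    cpaasc_fallback: str = _chem.CPAASC_FALLBACK

    def hash(self) -> str:
        """Stable digest of the configuration, recorded in run manifests."""
        def _enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: _enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, Mapping):
                return {str(k): _enc(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (set, frozenset)):
                return sorted(obj)
            return obj

        payload = json.dumps(_enc(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


DEFAULT_CONFIG = FeatureConfig()
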