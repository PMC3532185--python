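"""Mass, m/z, ppm-error and isoelectric-point calculators.

Residue mass tables and pK sets ship as plain-text data files under
``seedscape/data`` so alternates can be added without code changes.
Sequences containing residues without a defined mass or pK (B, J, O, U, X, Z)
yield ``None`` rather than a guessed value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

log = logging.getLogger(__name__)

#: Monoisotopic mass of water (Da).
WATER_MONO = 18.0105646
#: Mass of a proton (Da), used for charge-state arithmetic.
PROTON = 1.0072765
#: Carbamidomethylation of cysteine, the usual fixed alkylation modification.
CARBAMIDOMETHYL_C = 57.021464

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_IONIZABLE_SIDE_CHAINS = ("C", "D", "E", "H", "K", "R", "Y")
_BASIC_GROUPS = frozenset({"n_term", "H", "K", "R"})


def _read_data_table(filename: str) -> dict[str, float]:
    text = resources.files("seedscape.data").joinpath(filename).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        table[key] = float(value)
    return table


@dataclass(frozen=True)
class MassModel:
    """Residue mass tables plus the constants needed for peptide mass and m/z."""

    residue_mono: Mapping[str, float]
    residue_avg: Mapping[str, float]
    water_mono: float = WATER_MONO
    proton: float = PROTON
    fixed_mods: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "MassModel":
        return cls(
            residue_mono=_read_data_table("masses_monoisotopic.tsv"),
            residue_avg=_read_data_table("masses_average.tsv"),
        )

    def with_carbamidomethyl_c(self) -> "MassModel":
        """Return a copy with the fixed carbamidomethyl-C modification applied."""
        mods = dict(self.fixed_mods)
        mods["C"] = mods.get("C", 0.0) + CARBAMIDOMETHYL_C
        return replace(self, fixed_mods=mods)


_DEFAULT_MODEL: MassModel | None = None


def default_mass_model() -> MassModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = MassModel.default()
    return _DEFAULT_MODEL


def mono_mass(sequence: str, model: MassModel | None = None) -> float | None:
    """Monoisotopic neutral mass of ``sequence`` in Da.

    Returns ``None`` when any residue lacks a defined mass (ambiguous residues
    such as B/J/O/U/X/Z); the offending residue is logged.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    model = model or default_mass_model()
    total = model.water_mono
    for residue in sequence:
        mass = model.residue_mono.get(residue)
        if mass is None:
            log.debug("undefined residue mass %r in %r", residue, sequence)
            return None
        total += mass + model.fixed_mods.get(residue, 0.0)
    return total


def average_mass(sequence: str, model: MassModel | None = None) -> float | None:
    """Average (chemical) neutral mass of ``sequence`` in Da, or ``None``."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    model = model or default_mass_model()
    total = 18.01528
    for residue in sequence:
        mass = model.residue_avg.get(residue)
        if mass is None:
            return None
        total += mass + model.fixed_mods.get(residue, 0.0)
    return total


def mz_for_charge(neutral_mass: float, z: int, model: MassModel | None = None) -> float:
    """m/z of an ion with ``z`` added protons."""
    if z <= 0:
        raise ValueError(f"charge must be >= 1, got {z}")
    model = model or default_mass_model()
    return (neutral_mass + z * model.proton) / z


def neutral_mass_for_mz(mz: float, z: int, model: MassModel | None = None) -> float:
    """Inverse of :func:`mz_for_charge`."""
    if z <= 0:
        raise ValueError(f"charge must be >= 1, got {z}")
    model = model or default_mass_model()
    return mz * z - z * model.proton


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error of ``observed`` vs ``theoretical`` in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class PKSet:
    """pK values for the terminal groups and the seven ionizable side chains."""

    name: str
    n_term: float
    c_term: float
    side_chain: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, pk in [("n_term", self.n_term), ("c_term", self.c_term)] + list(
            self.side_chain.items()
        ):
            if not 0.0 < pk < 14.0:
                raise ValueError(f"pK for {label} out of (0, 14): {pk}")
        missing = set(_IONIZABLE_SIDE_CHAINS) - set(self.side_chain)
        if missing:
            raise ValueError(f"pK set {self.name!r} missing side chains {sorted(missing)}")

    @classmethod
    def load(cls, name: str = "bjellqvist") -> "PKSet":
        """Load a named pK set from the packaged data files."""
        table = _read_data_table(f"pk_{name.lower()}.tsv")
        return cls(
            name=name.lower(),
            n_term=table["n_term"],
            c_term=table["c_term"],
            side_chain={r: table[r] for r in _IONIZABLE_SIDE_CHAINS},
        )


_DEFAULT_PKSET: PKSet | None = None


def default_pkset() -> PKSet:
    global _DEFAULT_PKSET
    if _DEFAULT_PKSET is None:
        _DEFAULT_PKSET = PKSet.load("bjellqvist")
    return _DEFAULT_PKSET


def net_charge(sequence: str, ph: float, pkset: PKSet | None = None) -> float:
    """Net charge of ``sequence`` at ``ph`` under the Henderson–Hasselbalch model.

    Basic groups contribute ``1/(1 + 10^(pH - pK))``; acidic groups contribute
    ``-1/(1 + 10^(pK - pH))``. Composition-only: residue order is irrelevant.
    """
    pkset = pkset or default_pkset()
    groups: list[tuple[float, bool]] = [(pkset.n_term, True), (pkset.c_term, False)]
    for residue in sequence:
        pk = pkset.side_chain.get(residue)
        if pk is not None:
            groups.append((pk, residue in _BASIC_GROUPS))
    charge = 0.0
    for pk, basic in groups:
        if basic:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pk))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pk - ph))
    return charge


def isoelectric_point(
    sequence: str, pkset: PKSet | None = None, tol: float = 0.001
) -> float | None:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Returns ``None`` if the sequence contains residues outside the 20 canonical
    amino acids (their ionization behaviour is undefined).
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not set(sequence) <= CANONICAL_RESIDUES:
        log.debug("non-canonical residues in %r; pI undefined", sequence)
        return None
    pkset = pkset or default_pkset()
    lo, hi = 0.0, 14.0
    # net_charge is strictly decreasing in pH, so the zero crossing is unique.
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pkset) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
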