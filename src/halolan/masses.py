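"""Exact monoisotopic mass arithmetic for lanthipeptide species.

Every mature-species hypothesis in this package reduces to a sum of residue
masses plus one water per peptide chain plus a signed delta per
post-translational modification.  Lanthionine/methyllanthionine rings are
mass-neutral at closure; the mass change of a ring is entirely the dehydration
(-H2O) that precedes cyclization, so ring bookkeeping and dehydration
bookkeeping must never be double counted (see :func:`neutral_mass`).

The residue table uses the conventional monoisotopic values rounded at the
fifth decimal (the table every proteomics search engine ships); with the
proton mass below and half-up rounding at four decimals this reproduces
published high-resolution [M+nH]n+ values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "WATER",
    "PROTON",
    "RESIDUE_MASSES",
    "MOD_DELTAS",
    "SpeciesMass",
    "residue_mass",
    "chain_mass",
    "neutral_mass",
    "mz",
    "round_mz",
    "ppm_error",
    "apply_derivatization",
]

#: Monoisotopic mass of H2O (Da).
WATER = 18.010565

#: Monoisotopic mass of a proton (Da), positive-mode protonation.
PROTON = 1.0072765

#: Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021460,
    "A": 71.037110,
    "S": 87.032030,
    "P": 97.052760,
    "V": 99.068410,
    "T": 101.047680,
    "C": 103.009190,
    "L": 113.084060,
    "I": 113.084060,
    "N": 114.042930,
    "D": 115.026940,
    "Q": 128.058580,
    "K": 128.094960,
    "E": 129.042590,
    "M": 131.040490,
    "H": 137.058910,
    "F": 147.068410,
    "R": 156.101110,
    "Y": 163.063330,
    "W": 186.079310,
}

#: Signed mass deltas (Da) per modification event.
#:
#: ``thioether_ring`` carries the ring's dehydration; ring closure itself is
#: mass neutral.  ``chain_scission`` is backbone hydrolysis (+H2O, two new
#: termini).  Desulfurization deltas: a bridged thioether loses S and gains
#: 2H (net -29.956421); a free Cys thiol loses SH and gains H (net
#: -31.972071).  These derivatization deltas are provisional defaults and are
#: exposed in the rules config.
MOD_DELTAS: dict[str, float] = {
    "dehydration": -18.010565,
    "thioether_ring": -18.010565,
    "disulfide": -2.015650,
    "methylation": +14.015650,
    "acetylation": +42.010565,
    "hydroxylation": +15.994915,
    "chain_scission": +18.010565,
    "dtt_reduction": +2.015650,
    "desulfurization_bridge": -29.956421,
    "desulfurization_free_thiol": -31.972071,
}


class MassError(ValueError):
    """Unknown residue / modification kind or invalid mass arithmetic."""


@dataclass(frozen=True)
class SpeciesMass:
    """Neutral monoisotopic mass of a (possibly multi-chain) species.

    Attributes
    ----------
    neutral_mass : float
        Neutral monoisotopic mass in Da.
    n_chains : int
        Number of peptide chains (each contributes one water).
    mods : dict
        Per-modification event counts used in the mass (the trace).
    """

    neutral_mass: float
    n_chains: int
    mods: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise MassError(f"non-positive neutral mass {self.neutral_mass}")
        if self.n_chains < 1:
            raise MassError("a species needs at least one chain")


def dump_constants(path) -> None:
    """Serialize the mass-constant tables to a versioned YAML file.

    Audits can diff the file between releases; the derivatization deltas
    in particular are provisional and worth tracking.
    """
    import yaml
    payload = {
        "version": 1,
        "water": WATER,
        "proton": PROTON,
        "residue_masses": dict(sorted(RESIDUE_MASSES.items())),
        "modification_deltas": dict(sorted(MOD_DELTAS.items())),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def residue_mass(letter: str) -> float:
    """Monoisotopic residue mass of a one-letter amino acid code."""
    try:
        return RESIDUE_MASSES[letter]
    except KeyError:
        raise MassError(f"unknown residue {letter!r}") from None


def chain_mass(chain: str) -> float:
    """Residue-sum mass of one chain (no terminal water)."""
    if not chain:
        raise MassError("empty chain")
    return sum(residue_mass(c) for c in chain)


def neutral_mass(chains: list[str] | tuple[str, ...],
                 mods: dict[str, int] | None = None,
                 deltas: dict[str, float] | None = None) -> SpeciesMass:
    """Neutral monoisotopic mass of a multi-chain modified species.

    mass = sum of residue masses + n_chains * H2O + sum(count * delta).

    The caller is responsible for counting each ring either as one
    ``dehydration`` or as one ``thioether_ring`` (identical delta), never
    both.  Chain scission may equivalently be expressed by splitting the
    chain list (the extra water then enters through ``n_chains``) or by a
    ``chain_scission`` count on the unsplit chain; the two routes agree.

    Raises
    ------
    MassError
        On empty chains, unknown residues/modification kinds, or negative
        counts.
    """
    mods = dict(mods or {})
    table = MOD_DELTAS if deltas is None else deltas
    if not chains:
        raise MassError("species needs at least one chain")
    total = sum(chain_mass(c) for c in chains) + len(chains) * WATER
    for kind, count in mods.items():
        if kind not in table:
            raise MassError(f"unknown modification kind {kind!r}")
        if count < 0:
            raise MassError(f"negative count for {kind!r}")
        total += count * table[kind]
    return SpeciesMass(neutral_mass=total, n_chains=len(chains), mods=mods)


def mz(neutral: float, charge: int) -> float:
    """m/z of [M + zH]z+ for a neutral mass M."""
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    return (neutral + charge * PROTON) / charge


def round_mz(value: float, ndigits: int = 4) -> float:
    """Round half-up at `ndigits` decimals, the print convention for m/z."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def ppm_error(observed: float, calculated: float, signed: bool = False) -> float:
    """Relative mass deviation in parts per million.

    (observed - calculated) / calculated * 1e6; absolute value unless
    ``signed``.  The calculated mass is the denominator.
    """
    if calculated <= 0:
        raise MassError("calculated m/z must be positive")
    delta = (observed - calculated) / calculated * 1e6
    return delta if signed else abs(delta)


def apply_derivatization(species: SpeciesMass, treatment: str,
                         n_sites: int | None = None) -> SpeciesMass:
    """Mass shift of a chemical derivatization used for structure proofs.

    Treatments
    ----------
    ``dtt``
        Dithiothreitol reduction: +2.015650 Da per disulfide.  Requires the
        species trace to contain at least one disulfide; all are reduced.
    ``full_desulfurization``
        Every thioether bridge opened: -29.956421 Da per ring.
    ``partial_desulfurization``
        Exactly ``n_sites`` bridges opened.
    ``free_thiol_desulfurization``
        -31.972071 Da per unbridged Cys thiol; ``n_sites`` required.
    """
    mods = dict(species.mods)
    if treatment == "dtt":
        n = mods.get("disulfide", 0)
        if n < 1:
            raise MassError("dtt reduction requires at least one disulfide")
        mods["dtt_reduction"] = mods.get("dtt_reduction", 0) + n
        shift = n * MOD_DELTAS["dtt_reduction"]
    elif treatment in ("full_desulfurization", "partial_desulfurization"):
        n_rings = mods.get("thioether_ring", 0)
        if treatment == "full_desulfurization":
            n = n_rings
        else:
            if n_sites is None:
                raise MassError("partial_desulfurization needs n_sites")
            n = n_sites
        if n > n_rings:
            raise MassError(f"cannot desulfurize {n} of {n_rings} rings")
        mods["desulfurization_bridge"] = mods.get("desulfurization_bridge", 0) + n
        shift = n * MOD_DELTAS["desulfurization_bridge"]
    elif treatment == "free_thiol_desulfurization":
        if n_sites is None:
            raise MassError("free_thiol_desulfurization needs n_sites")
        mods["desulfurization_free_thiol"] = (
            mods.get("desulfurization_free_thiol", 0) + n_sites)
        shift = n_sites * MOD_DELTAS["desulfurization_free_thiol"]
    else:
        raise MassError(f"unknown treatment {treatment!r}")
    return SpeciesMass(neutral_mass=species.neutral_mass + shift,
                       n_chains=species.n_chains, mods=mods)
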