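"""Rule-guided enumeration of mature lanthipeptide species.

From a precursor (leader + core) this module generates every candidate
mature species allowed by class II lanthipeptide biosynthesis logic:

* leader cleavage hypotheses (explicit sites, or every site in the
  C-terminal half whose core keeps >= 1 Cys and >= 1 Ser/Thr);
* modification multisets — dehydrations of Ser/Thr, thioether rings
  (lanthionine from Ser, methyllanthionine from Thr, each consuming one
  dehydration), Cys-Cys disulfides, and capped tailoring modifications
  (methylation / acetylation / hydroxylation);
* ring topologies — all pairings of donor Ser/Thr with acceptor Cys,
  including adjacent-residue rings and crossing (intertwined) links;
* ring-internal backbone scissions, producing two antiparallel chains held
  together by the thioether bridges (the DADC subfamily).  A scission is
  hydrolysis (+H2O); only bonds bridged by at least one crosslink are cut,
  so the residue graph stays connected;
* exonucleolytic trimming of exposed termini, never removing a crosslinked
  residue.

Coordinates are 1-based on the core; ring spans are inclusive.  Chains are
contiguous core spans, so every species remembers where each residue sits
in the precursor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterable, Sequence

from .masses import MOD_DELTAS, WATER, neutral_mass, residue_mass

__all__ = [
    "Crosslink",
    "RingTopology",
    "PrecursorRecord",
    "CandidateSpecies",
    "EnumerationRules",
    "split_leader_core",
    "enumerate_mod_states",
    "enumerate_ring_topologies",
    "enumerate_scissions",
    "enumerate_trims",
    "build_candidate_library",
    "write_library_tsv",
]

logger = logging.getLogger(__name__)

DONORS = frozenset("ST")      # dehydratable, ring donors
ACCEPTOR = "C"                # thiol ring acceptor

#: modification kinds whose counts are enumerated
_TAILORING = ("methylation", "acetylation", "hydroxylation")


class RuleError(ValueError):
    """Invalid rules, topology, or library construction request."""


@dataclass(frozen=True, order=True)
class Crosslink:
    """One covalent crosslink between core positions i < j (1-based).

    kind: "Lan" (Ser-Cys thioether), "MeLan" (Thr-Cys thioether) or
    "disulfide" (Cys-Cys).
    """

    i: int
    j: int
    kind: str

    def __post_init__(self) -> None:
        if not 1 <= self.i < self.j:
            raise RuleError(f"crosslink needs 1 <= i < j, got ({self.i}, {self.j})")
        if self.kind not in ("Lan", "MeLan", "disulfide"):
            raise RuleError(f"unknown crosslink kind {self.kind!r}")

    @property
    def is_thioether(self) -> bool:
        return self.kind in ("Lan", "MeLan")

    def bridges(self, k: int) -> bool:
        """True if this link spans backbone bond k-(k+1)."""
        return self.i <= k < self.j


@dataclass(frozen=True)
class RingTopology:
    """A set of crosslinks on the core; crossing links are permitted."""

    crosslinks: tuple[Crosslink, ...] = ()

    def __post_init__(self) -> None:
        used: set[int] = set()
        for link in self.crosslinks:
            if link.i in used or link.j in used:
                raise RuleError(f"residue reused in topology: {link}")
            used.update((link.i, link.j))

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(p for l in self.crosslinks for p in (l.i, l.j))

    def validate_against(self, core: str) -> None:
        """Check residue chemistry: Lan S+C, MeLan T+C, disulfide C+C."""
        for link in self.crosslinks:
            if link.j > len(core):
                raise RuleError(f"{link} outside core of length {len(core)}")
            pair = {core[link.i - 1], core[link.j - 1]}
            ok = {"Lan": {"S", "C"}, "MeLan": {"T", "C"},
                  "disulfide": {"C"}}[link.kind]
            if pair != ok:
                raise RuleError(
                    f"{link.kind} link {link.i}-{link.j} pairs "
                    f"{core[link.i - 1]}/{core[link.j - 1]}")

    def to_string(self, core: str) -> str:
        """E.g. "T2-C10;C3-T9;T4-C7" (sorted by first position)."""
        parts = []
        for link in sorted(self.crosslinks):
            parts.append(f"{core[link.i - 1]}{link.i}-"
                         f"{core[link.j - 1]}{link.j}")
        return ";".join(parts)


@dataclass(frozen=True)
class PrecursorRecord:
    """A precursor split into leader and core at one hypothesized site."""

    id: str
    full_sequence: str
    cleavage_site: int  # 1-based position of the last leader residue

    def __post_init__(self) -> None:
        if not 0 < self.cleavage_site < len(self.full_sequence):
            raise RuleError(
                f"{self.id}: cleavage site {self.cleavage_site} outside "
                f"sequence of length {len(self.full_sequence)}")

    @property
    def leader(self) -> str:
        return self.full_sequence[: self.cleavage_site]

    @property
    def core(self) -> str:
        return self.full_sequence[self.cleavage_site:]


class CandidateSpecies:
    """A mature-peptide hypothesis: chains + topology + modifications + mass.

    Parameters
    ----------
    precursor_id : str
    core : str
        The core peptide the species derives from (coordinate system for
        spans and crosslinks).
    chains : sequence of (start, end)
        1-based inclusive core spans, one per chain, in core order.
    topology : RingTopology
    mods : mapping kind -> count
        Mass-contributing modification events.  ``thioether_ring`` counts
        rings (each ring's dehydration is part of its delta);
        ``dehydration`` counts *free* dehydrations (Dha/Dhb) only, so the
        two are never double counted.  Backbone scissions are NOT in mods:
        their +H2O enters through the per-chain water term.
    """

    __slots__ = ("precursor_id", "core", "chains", "topology", "_mods",
                 "n_scissions", "n_trimmed", "neutral_mass", "species_key")

    def __init__(self, precursor_id: str, core: str,
                 chains: Sequence[tuple[int, int]], topology: RingTopology,
                 mods: dict[str, int], n_scissions: int = 0,
                 n_trimmed: int = 0, validate: bool = True) -> None:
        self.precursor_id = precursor_id
        self.core = core
        self.chains = tuple(sorted(tuple(c) for c in chains))
        self.topology = topology
        self._mods = tuple(sorted((k, v) for k, v in mods.items() if v))
        self.n_scissions = n_scissions
        self.n_trimmed = n_trimmed
        if validate:
            self._check()
        sm = neutral_mass(list(self.chain_sequences), dict(self._mods))
        self.neutral_mass = sm.neutral_mass
        self.species_key = self._key()

    # -- derived views -------------------------------------------------
    @property
    def mods(self) -> dict[str, int]:
        return dict(self._mods)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def chain_sequences(self) -> tuple[str, ...]:
        return tuple(self.core[a - 1: b] for a, b in self.chains)

    @property
    def present_positions(self) -> frozenset[int]:
        return frozenset(p for a, b in self.chains for p in range(a, b + 1))

    @property
    def mass_key(self) -> tuple:
        """Dedup key for MS1: chain composition + mass at 1e-6 Da."""
        return (tuple(sorted(self.chain_sequences)),
                round(self.neutral_mass, 6))

    def _key(self) -> str:
        mods = ",".join(f"{k}:{v}" for k, v in self._mods)
        spans = "|".join(f"{a}-{b}" for a, b in self.chains)
        return (f"{self.precursor_id};core={self.core};chains={spans};"
                f"top={self.topology.to_string(self.core)};mods={mods}")

    # -- invariants ----------------------------------------------------
    def _check(self) -> None:
        if not self.chains:
            raise RuleError("species must keep at least one chain")
        for a, b in self.chains:
            if not 1 <= a <= b <= len(self.core):
                raise RuleError(f"chain span ({a},{b}) outside core")
        present = self.present_positions
        for link in self.topology.crosslinks:
            if link.i not in present or link.j not in present:
                raise RuleError(f"crosslink {link} references trimmed residue")
        self.topology.validate_against(self.core)
        if not self.is_connected():
            raise RuleError("residue graph is disconnected")
        mods = dict(self._mods)
        n_rings = sum(1 for l in self.topology.crosslinks if l.is_thioether)
        n_ss = sum(1 for l in self.topology.crosslinks if l.kind == "disulfide")
        if mods.get("thioether_ring", 0) != n_rings:
            raise RuleError("thioether_ring count does not match topology")
        if mods.get("disulfide", 0) != n_ss:
            raise RuleError("disulfide count does not match topology")

    def is_connected(self) -> bool:
        """Brute-force traversal of backbone bonds + crosslinks."""
        present = self.present_positions
        if not present:
            return False
        adj: dict[int, list[int]] = {p: [] for p in present}
        for a, b in self.chains:
            for k in range(a, b):
                adj[k].append(k + 1)
                adj[k + 1].append(k)
        for link in self.topology.crosslinks:
            adj[link.i].append(link.j)
            adj[link.j].append(link.i)
        seen = set()
        stack = [next(iter(present))]
        while stack:
            p = stack.pop()
            if p in seen:
                continue
            seen.add(p)
            stack.extend(q for q in adj[p] if q not in seen)
        return seen == present

    def __repr__(self) -> str:
        return (f"CandidateSpecies({'|'.join(self.chain_sequences)}, "
                f"top={self.topology.to_string(self.core)}, "
                f"mods={dict(self._mods)}, M={self.neutral_mass:.4f})")


@dataclass(frozen=True)
class EnumerationRules:
    """Bounds for the candidate generator.

    max_rings / max_disulfides cap the topology search on top of the
    residue-inventory feasibility bounds; tailoring caps default to one
    event each; max_scissions and max_trim bound the DADC / trimming
    expansion; library_cap aborts runaway libraries.
    """

    max_rings: int = 3
    max_disulfides: int = 1
    max_methylation: int = 1
    max_acetylation: int = 1
    max_hydroxylation: int = 1
    max_scissions: int = 1
    max_trim: int = 2
    library_cap: int = 500_000

    def validate(self) -> None:
        for name in ("max_rings", "max_disulfides", "max_methylation",
                     "max_acetylation", "max_hydroxylation", "max_scissions",
                     "max_trim", "library_cap"):
            if getattr(self, name) < 0:
                raise RuleError(f"{name} must be non-negative")


def split_leader_core(precursor_id: str, sequence: str,
                      sites: Iterable[int] | None = None
                      ) -> list[PrecursorRecord]:
    """Leader/core split hypotheses for one precursor sequence.

    With ``sites`` given (1-based positions of the last leader residue)
    each is passed through as one record.  Otherwise every position in the
    C-terminal half is hypothesized, keeping only cores that contain at
    least one Cys and at least one Ser/Thr (the minimum inventory for a
    thioether ring).  No valid site yields an empty list with a warning.
    """
    if len(sequence) < 2:
        raise RuleError(f"{precursor_id}: sequence too short to split")
    records = []
    if sites is not None:
        for s in sites:
            records.append(PrecursorRecord(precursor_id, sequence, s))
        return records
    for s in range(len(sequence) // 2, len(sequence)):
        core = sequence[s:]
        if ACCEPTOR in core and (set(core) & DONORS):
            records.append(PrecursorRecord(precursor_id, sequence, s))
    if not records:
        logger.warning("%s: no valid cleavage site (core needs Cys and "
                       "Ser/Thr)", precursor_id)
    return records


def enumerate_mod_states(core: str, rules: EnumerationRules | None = None
                         ) -> list[dict[str, int]]:
    """All modification multisets the core's residue inventory allows.

    Keys: ``dehydration`` (free Dha/Dhb), ``thioether_ring``, ``disulfide``
    and the tailoring kinds.  Bounds: free dehydrations + rings <= #Ser+#Thr;
    rings <= #Cys; disulfides <= floor((#Cys - rings)/2); tailoring counts
    up to their caps.  Zero-count kinds are omitted, so a core without
    S/T/C yields just the empty multiset.  Deterministic order.
    """
    rules = rules or EnumerationRules()
    rules.validate()
    n_donor = sum(core.count(a) for a in DONORS)
    n_cys = core.count(ACCEPTOR)
    if n_donor == 0 and n_cys == 0:
        # not a lanthipeptide substrate: no maturation chemistry at all
        return [{}]
    states = []
    for rings in range(0, min(n_cys, n_donor, rules.max_rings) + 1):
        for free_dehydr in range(0, n_donor - rings + 1):
            for ss in range(0, min((n_cys - rings) // 2,
                                   rules.max_disulfides) + 1):
                for met in range(rules.max_methylation + 1):
                    for ace in range(rules.max_acetylation + 1):
                        for hyd in range(rules.max_hydroxylation + 1):
                            mods = {"dehydration": free_dehydr,
                                    "thioether_ring": rings,
                                    "disulfide": ss,
                                    "methylation": met,
                                    "acetylation": ace,
                                    "hydroxylation": hyd}
                            states.append({k: v for k, v in mods.items() if v})
    # deterministic order, duplicates impossible by construction
    states.sort(key=lambda m: sorted(m.items()))
    return states


def enumerate_ring_topologies(core: str, n_rings: int, n_disulfides: int = 0
                              ) -> list[RingTopology]:
    """All chemically valid pairings for the requested link counts.

    Thioether rings pair one Ser/Thr donor with one Cys (Lan from Ser,
    MeLan from Thr); disulfides pair two of the remaining Cys.  Adjacent
    pairs and crossing links are allowed.  Infeasible counts give [].
    """
    donor_pos = [k + 1 for k, aa in enumerate(core) if aa in DONORS]
    cys_pos = [k + 1 for k, aa in enumerate(core) if aa == ACCEPTOR]
    if n_rings > min(len(donor_pos), len(cys_pos)):
        return []
    if n_disulfides > (len(cys_pos) - n_rings) // 2:
        return []
    if n_rings == 0 and n_disulfides == 0:
        return [RingTopology()]

    out = set()
    for ring_cys in combinations(cys_pos, n_rings):
        for ring_donors in permutations(donor_pos, n_rings):
            links = []
            for d, c in zip(ring_donors, ring_cys):
                kind = "Lan" if core[d - 1] == "S" else "MeLan"
                links.append(Crosslink(min(d, c), max(d, c), kind))
            rest = [c for c in cys_pos if c not in ring_cys]
            for ss_links in _cys_pairings(rest, n_disulfides):
                topo = tuple(sorted(links + ss_links))
                out.add(topo)
    return [RingTopology(t) for t in sorted(out)]


def _cys_pairings(cys: list[int], n_pairs: int) -> list[list[Crosslink]]:
    """All ways to form n_pairs disjoint Cys-Cys disulfides."""
    if n_pairs == 0:
        return [[]]
    out = []
    first, rest = cys[0], cys[1:]
    # pairings that use the first Cys
    for k, partner in enumerate(rest):
        remaining = rest[:k] + rest[k + 1:]
        for tail in _cys_pairings(remaining, n_pairs - 1):
            out.append([Crosslink(first, partner, "disulfide")] + tail)
    # pairings that skip it
    if len(rest) >= 2 * n_pairs:
        for tail in _cys_pairings(rest, n_pairs):
            out.append(tail)
    return out


def _bridged_bonds(candidate: CandidateSpecies) -> list[int]:
    """In-chain backbone bonds k-(k+1) spanned by >= 1 crosslink."""
    bonds = []
    links = candidate.topology.crosslinks
    for a, b in candidate.chains:
        for k in range(a, b):
            if any(l.bridges(k) for l in links):
                bonds.append(k)
    return bonds


def enumerate_scissions(candidate: CandidateSpecies, max_scissions: int = 1
                        ) -> list[CandidateSpecies]:
    """Backbone-hydrolysis variants inside ring spans (DADC maturation).

    Cuts are placed only on bonds bridged by at least one crosslink, so
    the product stays one connected species with an extra chain (+H2O,
    two new termini) per cut.  The uncut candidate itself is not included.
    """
    if max_scissions < 1 or not candidate.topology.crosslinks:
        return []
    out = []
    frontier = [candidate]
    for _ in range(max_scissions):
        nxt = []
        for cand in frontier:
            for k in _bridged_bonds(cand):
                chains = []
                for a, b in cand.chains:
                    if a <= k < b:
                        chains.extend([(a, k), (k + 1, b)])
                    else:
                        chains.append((a, b))
                try:
                    variant = CandidateSpecies(
                        cand.precursor_id, cand.core, chains, cand.topology,
                        cand.mods, n_scissions=cand.n_scissions + 1,
                        n_trimmed=cand.n_trimmed)
                except RuleError:
                    continue  # connectivity contract failed
                nxt.append(variant)
        # dedup cuts reached in different orders
        seen: dict[str, CandidateSpecies] = {}
        for v in nxt:
            seen.setdefault(v.species_key, v)
        frontier = list(seen.values())
        out.extend(frontier)
    uniq: dict[str, CandidateSpecies] = {}
    for v in out:
        uniq.setdefault(v.species_key, v)
    return sorted(uniq.values(), key=lambda c: c.species_key)


def enumerate_trims(candidate: CandidateSpecies, max_trim: int = 2
                    ) -> list[CandidateSpecies]:
    """Variants with up to ``max_trim`` residues removed from exposed termini.

    Models hydrolysis of terminal residues extending outside the rings by
    host aminopeptidases/carboxypeptidases.  A crosslinked residue is never
    removed, and no chain may vanish.  The untrimmed candidate is included
    (trim depth zero everywhere), so ``max_trim=0`` is the identity.

    In the library composition trims are applied only to candidates that
    carry at least one crosslink: for a linear unbridged peptide an
    N-terminal trim is indistinguishable from another leader-cleavage
    hypothesis and a C-terminal trim from a shorter gene product, so
    trimming them would only duplicate masses.  This function itself
    accepts any candidate.
    """
    if max_trim < 0:
        raise RuleError("max_trim must be >= 0")
    linked = candidate.topology.positions
    out: dict[str, CandidateSpecies] = {candidate.species_key: candidate}
    frontier = {candidate.species_key: candidate}
    for _ in range(max_trim):
        nxt: dict[str, CandidateSpecies] = {}
        for cand in frontier.values():
            for idx, (a, b) in enumerate(cand.chains):
                for new_span in ((a + 1, b), (a, b - 1)):
                    removed = a if new_span[0] == a + 1 else b
                    if removed in linked or new_span[0] > new_span[1]:
                        continue
                    chains = list(cand.chains)
                    chains[idx] = new_span
                    try:
                        variant = CandidateSpecies(
                            cand.precursor_id, cand.core, chains,
                            cand.topology, cand.mods,
                            n_scissions=cand.n_scissions,
                            n_trimmed=cand.n_trimmed + 1)
                    except RuleError:
                        continue
                    nxt.setdefault(variant.species_key, variant)
        frontier = nxt
        out.update(nxt)
    return sorted(out.values(), key=lambda c: c.species_key)


def build_candidate_library(precursors: Iterable[PrecursorRecord],
                            rules: EnumerationRules | None = None
                            ) -> list[CandidateSpecies]:
    """Compose the four enumerators into a deduplicated candidate library.

    Semantics: for each precursor hypothesis, modification multisets x
    ring topologies x (optional ring-internal scissions) x terminal trims
    (trims only on crosslinked candidates), deduplicated on the
    mass-and-chain-composition key — topological isomers of equal mass
    collapse for MS1 matching; the retained representative keeps a
    concrete topology for MS/MS prediction.

    Because the dedup key depends on the topology only through its
    existence, the default implementation never materialises the topology
    cross-product: it enumerates chain configurations (an optional cut
    bond plus per-terminus trim depths) and modification counts, admits a
    configuration iff the residue inventory of the retained positions can
    realise the requested ring/disulfide counts — with, for a cut, at
    least one link spanning the cut bond, which for a single cut is
    exactly the connectivity contract — and builds one deterministic
    witness topology per unique key.  With ``max_scissions > 1`` (where
    the spanning condition is no longer exact) it falls back to explicit
    enumeration.  Exceeding ``rules.library_cap`` raises RuleError.
    """
    rules = rules or EnumerationRules()
    rules.validate()
    library: dict[tuple, CandidateSpecies] = {}
    for prec in precursors:
        if rules.max_scissions <= 1:
            _fast_core_library(prec.id, prec.core, rules, library)
        else:
            _explicit_core_library(prec.id, prec.core, rules, library)
        if len(library) > rules.library_cap:
            raise RuleError(f"library cap {rules.library_cap} exceeded; "
                            "tighten enumeration bounds")
    return sorted(library.values(), key=lambda c: (c.neutral_mass,
                                                   c.species_key))


def _explicit_core_library(pid: str, core: str, rules: EnumerationRules,
                           library: dict) -> None:
    """Reference composition of the four enumerators (any scission count)."""
    for mods in enumerate_mod_states(core, rules):
        for topo in enumerate_ring_topologies(core,
                                              mods.get("thioether_ring", 0),
                                              mods.get("disulfide", 0)):
            try:
                base = CandidateSpecies(pid, core, [(1, len(core))], topo,
                                        mods)
            except RuleError:
                continue
            variants = [base]
            if rules.max_scissions and any(
                    l.is_thioether for l in topo.crosslinks):
                variants.extend(enumerate_scissions(base, rules.max_scissions))
            for var in variants:
                if topo.crosslinks:
                    for trimmed in enumerate_trims(var, rules.max_trim):
                        library.setdefault(trimmed.mass_key, trimmed)
                else:
                    library.setdefault(var.mass_key, var)


def _trim_vectors(n_termini: int, max_trim: int):
    """All per-terminus trim-depth vectors with total depth <= max_trim."""
    if n_termini == 0:
        yield ()
        return
    for depth in range(max_trim + 1):
        for rest in _trim_vectors(n_termini - 1, max_trim - depth):
            yield (depth,) + rest


def _fast_core_library(pid: str, core: str, rules: EnumerationRules,
                       library: dict) -> None:
    """Counting/witness implementation for max_scissions <= 1."""
    n = len(core)
    pre_mass = [0.0]
    pre_d = [0]
    pre_c = [0]
    for ch in core:
        pre_mass.append(pre_mass[-1] + residue_mass(ch))
        pre_d.append(pre_d[-1] + (ch in DONORS))
        pre_c.append(pre_c[-1] + (ch == ACCEPTOR))
    nd_core = pre_d[n]
    if nd_core == 0 and pre_c[n] == 0:
        # not a lanthipeptide substrate: the unmodified chain only
        sm = pre_mass[n] + WATER
        key = ((core,), round(sm, 6))
        if key not in library:
            library[key] = CandidateSpecies(pid, core, [(1, n)],
                                            RingTopology(), {})
        return

    def seg(a: int, b: int) -> tuple[float, int, int]:
        return (pre_mass[b] - pre_mass[a - 1], pre_d[b] - pre_d[a - 1],
                pre_c[b] - pre_c[a - 1])

    # chain configurations: (chains, cut bond or None, n residues trimmed)
    configs: list[tuple[tuple[tuple[int, int], ...], int | None, int]] = []
    for tn, tc in _trim_vectors(2, rules.max_trim):
        a, b = 1 + tn, n - tc
        if a <= b:
            configs.append((((a, b),), None, tn + tc))
    if rules.max_scissions >= 1:
        for k in range(1, n):
            for t1, t2, t3, t4 in _trim_vectors(4, rules.max_trim):
                a1, b1, a2, b2 = 1 + t1, k - t2, k + 1 + t3, n - t4
                if a1 <= b1 and a2 <= b2:
                    configs.append((((a1, b1), (a2, b2)), k,
                                    t1 + t2 + t3 + t4))

    deltas = MOD_DELTAS
    for chains, cut, ntrim in configs:
        segs = [seg(a, b) for a, b in chains]
        base_mass = sum(s[0] for s in segs) + len(chains) * WATER
        d_p = sum(s[1] for s in segs)
        c_p = sum(s[2] for s in segs)
        chain_seqs = tuple(core[a - 1: b] for a, b in chains)
        key_chains = tuple(sorted(chain_seqs))
        for r in range(0, min(d_p, c_p, rules.max_rings) + 1):
            for s in range(0, min((c_p - r) // 2, rules.max_disulfides) + 1):
                if cut is not None:
                    if r < 1:
                        continue  # scission requires a thioether ring
                    d_l, c_l = segs[0][1], segs[0][2]
                    d_r, c_r = segs[1][1], segs[1][2]
                    ring_spans = (d_l >= 1 and c_r >= 1) or \
                                 (d_r >= 1 and c_l >= 1)
                    ss_spans = s >= 1 and c_l >= 1 and c_r >= 1
                    if not (ring_spans or ss_spans):
                        continue
                elif ntrim > 0 and r + s == 0:
                    continue  # trims only on crosslinked species
                fixed = base_mass + r * deltas["thioether_ring"] \
                    + s * deltas["disulfide"]
                for f in range(0, nd_core - r + 1):
                    for met in range(rules.max_methylation + 1):
                        for ace in range(rules.max_acetylation + 1):
                            for hyd in range(rules.max_hydroxylation + 1):
                                mass = fixed + f * deltas["dehydration"] \
                                    + met * deltas["methylation"] \
                                    + ace * deltas["acetylation"] \
                                    + hyd * deltas["hydroxylation"]
                                key = (key_chains, round(mass, 6))
                                if key in library:
                                    continue
                                mods = {"dehydration": f,
                                        "thioether_ring": r,
                                        "disulfide": s,
                                        "methylation": met,
                                        "acetylation": ace,
                                        "hydroxylation": hyd}
                                topo = _witness_topology(core, chains, cut,
                                                         r, s)
                                library[key] = CandidateSpecies(
                                    pid, core, chains, topo,
                                    {k: v for k, v in mods.items() if v},
                                    n_scissions=0 if cut is None else 1,
                                    n_trimmed=ntrim)


def _witness_topology(core: str, chains: tuple[tuple[int, int], ...],
                      cut: int | None, r: int, s: int) -> RingTopology:
    """One deterministic topology realising (r rings, s disulfides).

    Smallest-position pairing; for a cut species the first link is chosen
    to span the cut bond so the two chains stay covalently connected.
    """
    donors = [p for a, b in chains for p in range(a, b + 1)
              if core[p - 1] in DONORS]
    cys = [p for a, b in chains for p in range(a, b + 1)
           if core[p - 1] == ACCEPTOR]
    links: list[Crosslink] = []
    r_left, s_left = r, s

    def ring(d: int, c: int) -> Crosslink:
        kind = "Lan" if core[d - 1] == "S" else "MeLan"
        return Crosslink(min(d, c), max(d, c), kind)

    if cut is not None:
        d_l = [p for p in donors if p <= cut]
        d_r = [p for p in donors if p > cut]
        c_l = [p for p in cys if p <= cut]
        c_r = [p for p in cys if p > cut]
        if r_left and d_l and c_r:
            links.append(ring(d_l[0], c_r[0]))
            donors.remove(d_l[0])
            cys.remove(c_r[0])
            r_left -= 1
        elif r_left and d_r and c_l:
            links.append(ring(d_r[0], c_l[0]))
            donors.remove(d_r[0])
            cys.remove(c_l[0])
            r_left -= 1
        elif s_left and c_l and c_r:
            links.append(Crosslink(c_l[0], c_r[0], "disulfide"))
            cys.remove(c_l[0])
            cys.remove(c_r[0])
            s_left -= 1
        else:
            raise RuleError("no spanning link possible")  # pragma: no cover
    for _ in range(r_left):
        links.append(ring(donors.pop(0), cys.pop(0)))
    for _ in range(s_left):
        links.append(Crosslink(cys.pop(0), cys.pop(0), "disulfide"))
    return RingTopology(tuple(sorted(links)))


def write_library_tsv(library: list[CandidateSpecies],
                      path: str | Path) -> None:
    """TSV export: species_key, chains, topology, mods, neutral mass."""
    with open(path, "w") as fh:
        fh.write("species_key\tprecursor_id\tchains\ttopology\tmods\t"
                 "n_chains\tneutral_mass\n")
        for cand in library:
            mods = ",".join(f"{k}:{v}" for k, v in sorted(cand.mods.items()))
            fh.write(f"{cand.species_key}\t{cand.precursor_id}\t"
                     f"{'|'.join(cand.chain_sequences)}\t"
                     f"{cand.topology.to_string(cand.core)}\t{mods}\t"
                     f"{cand.n_chains}\t{cand.neutral_mass:.6f}\n")
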