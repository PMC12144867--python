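"""Candidate enumeration: cleavage, mod states, topologies, DADC, trims.

The library oracle here is deliberately naive and self-contained: it
re-derives the candidate space with its own topology pairing, its own
graph-connectivity test (networkx) and its own mass arithmetic straight
from the residue table, then compares (chain sequences, mass) key sets
with `build_candidate_library`.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from halolan.enumeration import (CandidateSpecies, Crosslink,
                                 EnumerationRules, PrecursorRecord, RuleError,
                                 RingTopology, build_candidate_library,
                                 enumerate_mod_states,
                                 enumerate_ring_topologies,
                                 enumerate_scissions, enumerate_trims,
                                 split_leader_core)
from halolan.masses import MOD_DELTAS, RESIDUE_MASSES, WATER

DONORS = set("ST")


# --------------------------------------------------------------------------
# independent oracle machinery

def oracle_topologies(core, r, s):
    """All crosslink sets: r thioethers (donor x Cys) + s disulfides."""
    donors = [i + 1 for i, c in enumerate(core) if c in DONORS]
    cys = [i + 1 for i, c in enumerate(core) if c == "C"]
    out = set()
    for dsub in itertools.permutations(donors, r):
        for csub in itertools.combinations(cys, r):
            links = []
            for d, c in zip(dsub, csub):
                kind = "Lan" if core[d - 1] == "S" else "MeLan"
                links.append((min(d, c), max(d, c), kind))
            rest = [c for c in cys if c not in csub]
            for ss in oracle_cys_pairings(rest, s):
                out.add(frozenset(links + ss))
    return out


def oracle_cys_pairings(cys, s):
    if s == 0:
        return [[]]
    out = []
    for pair in itertools.combinations(cys, 2):
        rest = [c for c in cys if c not in pair]
        for tail in oracle_cys_pairings(rest, s - 1):
            cand = [(pair[0], pair[1], "disulfide")] + tail
            out.append(cand)
    # dedupe orderings
    uniq = {frozenset(p) for p in out}
    return [sorted(u) for u in uniq]


def oracle_connected(chains, links):
    g = nx.Graph()
    for a, b in chains:
        g.add_nodes_from(range(a, b + 1))
        g.add_edges_from((k, k + 1) for k in range(a, b))
    present = set(g.nodes)
    for i, j, _ in links:
        if i not in present or j not in present:
            return False
    g.add_edges_from((i, j) for i, j, _ in links)
    return nx.is_connected(g)


def oracle_scission_variants(chains, links, max_cuts):
    """All chain tuples reachable by cutting in-chain bonds, staying
    connected (cuts are only possible inside crosslink spans)."""
    frontier = {chains}
    reached = set()
    for _ in range(max_cuts):
        nxt = set()
        for ch in frontier:
            for idx, (a, b) in enumerate(ch):
                for k in range(a, b):
                    new = list(ch)
                    new[idx:idx + 1] = [(a, k), (k + 1, b)]
                    new_t = tuple(sorted(new))
                    if oracle_connected(new_t, links):
                        nxt.add(new_t)
        reached |= nxt
        frontier = nxt
    return reached


def oracle_trim_variants(chains, links, max_trim):
    """Chain tuples reachable by stepwise terminal trimming that never
    removes a crosslinked residue and never empties a chain."""
    linked = {p for i, j, _ in links for p in (i, j)}
    reached = {chains}
    frontier = {chains}
    for _ in range(max_trim):
        nxt = set()
        for ch in frontier:
            for idx, (a, b) in enumerate(ch):
                for na, nb in ((a + 1, b), (a, b - 1)):
                    removed = a if na == a + 1 else b
                    if removed in linked or na > nb:
                        continue
                    new = list(ch)
                    new[idx] = (na, nb)
                    nxt.add(tuple(sorted(new)))
        frontier = nxt - reached
        reached |= nxt
    return reached


def oracle_library_keys(core, rules):
    """Brute-force (chain sequences, mass) key set for one core."""
    nd = sum(core.count(a) for a in DONORS)
    nc = core.count("C")
    if nd == 0 and nc == 0:  # no maturation chemistry applies
        mass = sum(RESIDUE_MASSES[c] for c in core) + WATER
        return {((core,), round(mass, 6))}
    keys = set()
    whole = ((1, len(core)),)
    for r in range(min(nd, nc, rules.max_rings) + 1):
        for s in range(min((nc - r) // 2, rules.max_disulfides) + 1):
            for topo in oracle_topologies(core, r, s):
                has_ring = any(k != "disulfide" for _, _, k in topo)
                shapes = {whole}
                if has_ring and rules.max_scissions:
                    shapes |= oracle_scission_variants(whole, topo,
                                                       rules.max_scissions)
                trimmed = set()
                for ch in shapes:
                    if topo:
                        trimmed |= oracle_trim_variants(ch, topo,
                                                        rules.max_trim)
                    else:
                        trimmed.add(ch)
                for ch in trimmed:
                    if not oracle_connected(ch, topo):
                        continue
                    seqs = tuple(sorted(core[a - 1: b] for a, b in ch))
                    base = sum(RESIDUE_MASSES[c] for s_ in seqs for c in s_)
                    base += len(ch) * WATER
                    for f in range(nd - r + 1):
                        for met in range(rules.max_methylation + 1):
                            for ace in range(rules.max_acetylation + 1):
                                for hyd in range(rules.max_hydroxylation + 1):
                                    mass = (base - (f + r) * WATER
                                            + s * MOD_DELTAS["disulfide"]
                                            + met * MOD_DELTAS["methylation"]
                                            + ace * MOD_DELTAS["acetylation"]
                                            + hyd * MOD_DELTAS["hydroxylation"])
                                    keys.add((seqs, round(mass, 6)))
    return keys


def library_keys(core, rules):
    prec = PrecursorRecord("p", "MA" + core, 2)
    lib = build_candidate_library([prec], rules)
    return {(tuple(sorted(c.chain_sequences)), round(c.neutral_mass, 6))
            for c in lib}


# --------------------------------------------------------------------------

class TestSplitLeaderCore:
    def test_explicit_sites_pass_through(self):
        recs = split_leader_core("p", "MKKDCTRYSF", sites=[4, 5, 6])
        assert [r.core for r in recs] == ["CTRYSF", "TRYSF", "RYSF"]
        assert all(r.leader + r.core == "MKKDCTRYSF" for r in recs)

    def test_default_scan_requires_cys_and_ser_thr(self):
        recs = split_leader_core("p", "MAAAAAAACTS")
        assert recs  # cores with C and S/T exist
        for r in recs:
            assert "C" in r.core and (set(r.core) & DONORS)
            assert r.cleavage_site >= len(r.full_sequence) // 2

    def test_no_valid_site_gives_empty_list(self, caplog):
        assert split_leader_core("p", "MAAAAAAAAK") == []


class TestModStates:
    def test_includes_single_dehydration(self):
        states = enumerate_mod_states("CTRYSF")
        assert {"dehydration": 1} in states
        assert {"thioether_ring": 1} in states

    def test_core_without_reactive_residues(self):
        assert enumerate_mod_states("ARG") == [{}]

    @pytest.mark.parametrize("core", ["CTRYSF", "STCC", "TTSSCC", "ACDEFGHA"])
    def test_count_matches_nested_loop_oracle(self, core):
        rules = EnumerationRules()
        nd = sum(core.count(a) for a in DONORS)
        nc = core.count("C")
        expected = 0
        for r in range(min(nd, nc, rules.max_rings) + 1):
            for f in range(nd - r + 1):
                for s in range(min((nc - r) // 2, rules.max_disulfides) + 1):
                    expected += ((rules.max_methylation + 1)
                                 * (rules.max_acetylation + 1)
                                 * (rules.max_hydroxylation + 1))
        assert len(enumerate_mod_states(core, rules)) == expected

    def test_deterministic_order(self):
        assert enumerate_mod_states("STCC") == enumerate_mod_states("STCC")


class TestRingTopologies:
    def test_includes_published_sallan_ring(self):
        topos = enumerate_ring_topologies("CTRYSF", 1)
        assert any(t.crosslinks == (Crosslink(1, 5, "Lan"),) for t in topos)

    def test_zero_rings_is_single_empty_topology(self):
        topos = enumerate_ring_topologies("CTRYSF", 0)
        assert len(topos) == 1 and topos[0].crosslinks == ()

    def test_infeasible_counts_empty(self):
        assert enumerate_ring_topologies("CTRYSF", 2) == []
        assert enumerate_ring_topologies("CTRYSF", 0, 1) == []

    @pytest.mark.parametrize("core,r,s", [
        ("STCC", 1, 0), ("STCC", 2, 0), ("STCC", 0, 1), ("STCCC", 1, 1),
        ("TSTSCC", 2, 0), ("CSCTC", 1, 1),
    ])
    def test_matches_brute_force_pairing(self, core, r, s):
        got = {frozenset((l.i, l.j, l.kind) for l in t.crosslinks)
               for t in enumerate_ring_topologies(core, r, s)}
        assert got == oracle_topologies(core, r, s)

    def test_chemistry_validation(self):
        with pytest.raises(RuleError):
            RingTopology((Crosslink(1, 2, "Lan"),)).validate_against("CC")
        with pytest.raises(RuleError):
            RingTopology((Crosslink(1, 2, "Lan"), Crosslink(2, 3, "Lan")))


class TestScissions:
    def test_linear_peptide_yields_none(self):
        cand = CandidateSpecies("p", "ACDEF", [(1, 5)], RingTopology(), {})
        assert enumerate_scissions(cand) == []

    def test_cut_inside_rings_stays_connected(self):
        core = "ATCTYGCPTCDA"  # rings 2-10, 3-9, 4-7 bridge bonds 4..7
        topo = RingTopology((Crosslink(2, 10, "MeLan"),
                             Crosslink(3, 9, "MeLan"),
                             Crosslink(4, 7, "MeLan")))
        cand = CandidateSpecies("p", core, [(1, 12)], topo,
                                {"thioether_ring": 3})
        variants = enumerate_scissions(cand)
        assert all(v.n_chains == 2 and v.is_connected() for v in variants)
        assert any(v.chains == ((1, 5), (6, 12)) for v in variants)

    def test_cut_outside_ring_span_discarded(self):
        core = "SACAAA"
        topo = RingTopology((Crosslink(1, 3, "Lan"),))
        cand = CandidateSpecies("p", core, [(1, 6)], topo,
                                {"thioether_ring": 1})
        variants = enumerate_scissions(cand)
        # only bonds 1-2 and 2-3 are bridged
        assert {v.chains for v in variants} == \
            {((1, 1), (2, 6)), ((1, 2), (3, 6))}

    def test_termini_count_is_twice_chain_count(self, larlan_a2):
        for cand in [larlan_a2] + enumerate_scissions(larlan_a2, 1):
            assert 2 * cand.n_chains == sum(2 for _ in cand.chains)


class TestTrims:
    def test_sallan_a1_minus_asp_is_sallan_a2(self, sallan_a2):
        a1 = CandidateSpecies("sallan_A1", "DCTRYSF", [(1, 7)],
                              RingTopology((Crosslink(2, 6, "Lan"),)),
                              {"thioether_ring": 1})
        variants = enumerate_trims(a1, 1)
        trimmed = [v for v in variants if v.chains == ((2, 7),)]
        assert len(trimmed) == 1
        assert a1.neutral_mass - trimmed[0].neutral_mass == \
            pytest.approx(115.0269, abs=1e-4)
        assert trimmed[0].neutral_mass == \
            pytest.approx(sallan_a2.neutral_mass, abs=1e-6)

    def test_never_removes_ring_residue(self):
        cand = CandidateSpecies("p", "CTRYSF", [(1, 6)],
                                RingTopology((Crosslink(1, 5, "Lan"),)),
                                {"thioether_ring": 1})
        variants = enumerate_trims(cand, 3)
        # N-terminus is Cys1 (linked): only C-terminal Phe6 is exposed
        assert {v.chains for v in variants} == {((1, 6),), ((1, 5),)}

    def test_max_trim_zero_is_identity(self, larlan_a2):
        assert enumerate_trims(larlan_a2, 0) == [larlan_a2]


class TestLibrary:
    RULES = [
        EnumerationRules(max_rings=2, max_disulfides=1, max_methylation=1,
                         max_acetylation=1, max_hydroxylation=1,
                         max_scissions=1, max_trim=2),
        EnumerationRules(max_rings=2, max_disulfides=2, max_methylation=2,
                         max_acetylation=0, max_hydroxylation=1,
                         max_scissions=2, max_trim=2),
    ]
    CORES = ["CTRYSF", "STCTYGCP", "TCCS", "SCTSC", "ADEFG", "CCSSTT"]

    @pytest.mark.parametrize("core", CORES)
    @pytest.mark.parametrize("rules", RULES, ids=["one_cut", "two_cuts"])
    def test_equals_brute_force(self, core, rules):
        assert library_keys(core, rules) == oracle_library_keys(core, rules)

    def test_byte_identical_determinism(self, tmp_path):
        from halolan.enumeration import write_library_tsv
        prec = split_leader_core("p", "MAAEDLSAGCTRYSFST")
        blobs = []
        for k in (1, 2):
            lib = build_candidate_library(prec, EnumerationRules())
            path = tmp_path / f"lib{k}.tsv"
            write_library_tsv(lib, path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]

    def test_contains_published_species(self):
        prec = PrecursorRecord("SalA", "MSDLNACTRYSF", 6)
        lib = build_candidate_library([prec], EnumerationRules())
        masses = {round(c.neutral_mass, 4) for c in lib}
        assert 757.3217 in masses or 757.3218 in masses

    def test_cap_exceeded_raises(self):
        rules = EnumerationRules(library_cap=3)
        with pytest.raises(RuleError, match="cap"):
            build_candidate_library(
                [PrecursorRecord("p", "MACTRYSFST", 2)], rules)

    def test_empty_precursor_list(self):
        assert build_candidate_library([], EnumerationRules()) == []


class TestDadcMassLaw:
    def test_ring_plus_internal_scission_is_mass_neutral(self):
        """Over many random cores: (ring, cut inside it) has the same mass
        as the unmodified linear chain."""
        rng = np.random.default_rng(17)
        letters = list(RESIDUE_MASSES)
        checked = 0
        while checked < 1000:
            n = int(rng.integers(4, 14))
            core = "".join(rng.choice(letters, size=n))
            donors = [i + 1 for i, c in enumerate(core) if c in DONORS]
            cys = [i + 1 for i, c in enumerate(core) if c == "C"]
            if not donors or not cys:
                continue
            d = int(rng.choice(donors))
            c = int(rng.choice(cys))
            if abs(d - c) < 2:
                continue
            i, j = min(d, c), max(d, c)
            kind = "Lan" if core[d - 1] == "S" else "MeLan"
            k = int(rng.integers(i, j))  # bond inside the ring span
            topo = RingTopology((Crosslink(i, j, kind),))
            cut = CandidateSpecies("p", core, [(1, k), (k + 1, n)], topo,
                                   {"thioether_ring": 1}, n_scissions=1)
            linear = CandidateSpecies("p", core, [(1, n)], RingTopology(), {})
            assert cut.neutral_mass == pytest.approx(linear.neutral_mass,
                                                     abs=1e-9)
            checked += 1


class TestSpeciesInvariants:
    def test_disconnected_species_rejected(self):
        with pytest.raises(RuleError, match="disconnected"):
            CandidateSpecies("p", "ACDEFG", [(1, 3), (4, 6)], RingTopology(),
                             {}, n_scissions=1)

    def test_mod_counts_must_match_topology(self):
        topo = RingTopology((Crosslink(1, 5, "Lan"),))
        with pytest.raises(RuleError):
            CandidateSpecies("p", "CTRYSF", [(1, 6)], topo, {})

    def test_crosslink_to_trimmed_residue_rejected(self):
        topo = RingTopology((Crosslink(1, 5, "Lan"),))
        with pytest.raises(RuleError):
            CandidateSpecies("p", "CTRYSF", [(1, 4)], topo,
                             {"thioether_ring": 1})
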