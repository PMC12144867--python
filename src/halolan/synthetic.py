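"""Synthetic precursors, planted mature species, and noisy MS data.

Everything the pipeline consumes can be generated here with known ground
truth, so each stage is testable offline:

* precursors: Met-initiated leaders plus short cores (default 6-15
  residues) drawn from a Ser/Thr/Cys-enriched composition, the hallmark of
  haloarchaeal lanthipeptide cores;
* a bacterial-style background set with a shifted composition (more K/I/L,
  less D/V/R/P) for the bias statistics;
* one true mature species per precursor, drawn from the precursor's own
  rule-based enumeration space (so the matching library provably contains
  it), including two-chain ring-scission species at a configurable rate;
* MS1 peak lists with Gaussian ppm mass error on planted peaks plus
  uniform decoys, and MGF MS/MS spectra over a random subset of each
  species' predicted fragments.

All randomness flows through one numpy Generator seeded from the config;
identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import SequenceRecord
from .enumeration import (CandidateSpecies, EnumerationRules,
                          enumerate_mod_states, enumerate_ring_topologies,
                          enumerate_scissions, enumerate_trims)
from .masses import PROTON
from .matching import predict_fragments

__all__ = [
    "SyntheticConfig",
    "generate_precursors",
    "generate_background",
    "plant_species",
    "simulate_ms1",
    "simulate_ms2",
    "write_fixtures",
    "PAPER_EXAMPLES",
]

# Core composition: S/T/C enriched (~36% combined), the rest uniform-ish.
_CORE_WEIGHTS = {
    "S": 0.14, "T": 0.10, "C": 0.12, "G": 0.06, "A": 0.06, "V": 0.05,
    "D": 0.05, "P": 0.05, "R": 0.05, "Y": 0.04, "F": 0.04, "I": 0.04,
    "L": 0.04, "N": 0.03, "E": 0.03, "K": 0.03, "Q": 0.02, "H": 0.02,
    "M": 0.02, "W": 0.01,
}

# Leader composition: generic acidic-leaning leader.
_LEADER_WEIGHTS = {
    "A": 0.09, "D": 0.08, "E": 0.10, "L": 0.09, "S": 0.07, "V": 0.07,
    "G": 0.07, "I": 0.06, "T": 0.05, "N": 0.05, "Q": 0.05, "K": 0.05,
    "F": 0.04, "P": 0.04, "R": 0.04, "Y": 0.03, "M": 0.03, "H": 0.03,
    "W": 0.02, "C": 0.04,
}

# Background ("bacterial") composition: shifted toward K/I/L/N/Q, away from
# D/V/R/P, mirroring the mesophile-vs-halophile contrast.
_BACKGROUND_WEIGHTS = {
    "A": 0.08, "D": 0.04, "E": 0.06, "L": 0.10, "S": 0.07, "V": 0.05,
    "G": 0.07, "I": 0.08, "T": 0.06, "N": 0.05, "Q": 0.04, "K": 0.08,
    "F": 0.05, "P": 0.03, "R": 0.03, "Y": 0.03, "M": 0.03, "H": 0.02,
    "W": 0.01, "C": 0.02,
}


@dataclass
class SyntheticConfig:
    """Knobs for the generator; defaults are the study-like conditions."""

    seed: int = 0
    n_precursors: int = 50
    leader_length: tuple[int, int] = (15, 30)
    core_length: tuple[int, int] = (6, 15)
    p_ring: float = 0.8          # chance a planted species has >= 1 ring
    p_disulfide: float = 0.1
    p_methylation: float = 0.1
    p_scission: float = 0.25     # chance a ringed species is cut (DADC)
    ms1_noise_ppm: float = 2.0
    n_decoys: int = 200
    decoy_mz_range: tuple[float, float] = (300.0, 1500.0)
    ms2_fragment_fraction: float = 0.7
    ms2_noise_ppm: float = 5.0
    ms2_n_noise_peaks: int = 10
    #: Enumeration bounds forming a closed world with the planted
    #: modification inventory: up to two rings, one disulfide, one
    #: methylation, one ring-internal scission, one terminal trim.
    #: Acetylation/hydroxylation are not planted, so they are not
    #: enumerated on synthetic data either.
    rules: EnumerationRules = field(default_factory=lambda: EnumerationRules(
        max_rings=2, max_disulfides=1, max_methylation=1,
        max_acetylation=0, max_hydroxylation=0, max_scissions=1,
        max_trim=1))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_seq(rng: np.random.Generator, length: int,
              weights: dict[str, float]) -> str:
    letters = list(weights)
    p = np.array([weights[a] for a in letters])
    p = p / p.sum()
    return "".join(rng.choice(letters, size=length, p=p))


def generate_precursors(config: SyntheticConfig
                        ) -> tuple[list[SequenceRecord], list[dict]]:
    """Synthetic LanA precursors plus a truth table.

    Each entry is leader + core; the core is redrawn until it contains at
    least one Cys and one Ser/Thr (the enumerable minimum).  The truth
    table records the true cleavage site (1-based last leader residue).
    """
    rng = config.rng()
    records, truth = [], []
    for k in range(config.n_precursors):
        llen = int(rng.integers(config.leader_length[0],
                                config.leader_length[1] + 1))
        clen = int(rng.integers(config.core_length[0],
                                config.core_length[1] + 1))
        leader = "M" + _draw_seq(rng, llen - 1, _LEADER_WEIGHTS)
        while True:
            core = _draw_seq(rng, clen, _CORE_WEIGHTS)
            if "C" in core and (set(core) & set("ST")):
                break
        pid = f"synA{k:04d}"
        records.append(SequenceRecord(id=pid, sequence=leader + core,
                                      set_label="synthetic_LanA",
                                      source="synthetic"))
        truth.append({"id": pid, "cleavage_site": llen, "leader": leader,
                      "core": core})
    return records, truth


def generate_background(config: SyntheticConfig, n: int = 100,
                        length_shift: int = 7) -> list[SequenceRecord]:
    """Background ("bacterial") sequence set with shifted composition.

    Lengths are drawn longer than the focal precursors by ``length_shift``
    on average, so length statistics have a planted difference too.
    """
    rng = np.random.default_rng(config.seed + 1)
    lo = config.leader_length[0] + config.core_length[0] + length_shift
    hi = config.leader_length[1] + config.core_length[1] + length_shift
    out = []
    for k in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append(SequenceRecord(id=f"synB{k:04d}",
                                  sequence=_draw_seq(rng, length,
                                                     _BACKGROUND_WEIGHTS),
                                  set_label="synthetic_bacterial_LanA",
                                  source="synthetic"))
    return out


def _raw_species(pid: str, core: str, rules: EnumerationRules
                 ) -> list[CandidateSpecies]:
    """Undeduplicated enumeration space for one core (ground-truth pool).

    The matching library collapses mass-degenerate isomers onto one
    representative; planted truths are drawn from the raw space so ringed
    and scissioned structures stay available, and recovery is judged by
    mass (MS1 cannot distinguish mass-degenerate multisets).
    """
    out = []
    for mods in enumerate_mod_states(core, rules):
        for topo in enumerate_ring_topologies(core,
                                              mods.get("thioether_ring", 0),
                                              mods.get("disulfide", 0)):
            try:
                base = CandidateSpecies(pid, core, [(1, len(core))], topo,
                                        mods)
            except Exception:
                continue
            variants = [base]
            if rules.max_scissions and any(
                    l.is_thioether for l in topo.crosslinks):
                variants.extend(enumerate_scissions(base, rules.max_scissions))
            for var in variants:
                if topo.crosslinks:
                    out.extend(enumerate_trims(var, rules.max_trim))
                else:
                    out.append(var)
    return out


def plant_species(truth: list[dict], config: SyntheticConfig
                  ) -> list[CandidateSpecies]:
    """Pick one true mature species per precursor from its own rule space.

    Ring/disulfide/scission choices follow the configured probabilities but
    always respect the core's residue inventory, so every truth is present
    (up to mass degeneracy) in the library `build_candidate_library` builds
    with the same rules.
    """
    rng = np.random.default_rng(config.seed + 2)
    truths = []
    for row in truth:
        pool = _raw_species(row["id"], row["core"], config.rules)
        ringed = [c for c in pool
                  if any(l.is_thioether for l in c.topology.crosslinks)]
        if ringed and rng.random() < config.p_ring:
            chosen = ringed
            if rng.random() < config.p_scission:
                cut = [c for c in chosen if c.n_chains > 1]
                chosen = cut or [c for c in chosen if c.n_chains == 1]
            else:
                chosen = [c for c in chosen if c.n_chains == 1]
            if rng.random() >= config.p_disulfide:
                no_ss = [c for c in chosen if not c.mods.get("disulfide")]
                chosen = no_ss or chosen
        else:
            chosen = [c for c in pool if not c.topology.crosslinks] or pool
        if rng.random() >= config.p_methylation:
            no_met = [c for c in chosen if not c.mods.get("methylation")]
            chosen = no_met or chosen
        else:
            met = [c for c in chosen if c.mods.get("methylation")]
            chosen = met or chosen
        truths.append(chosen[int(rng.integers(len(chosen)))])
    return truths


def simulate_ms1(truths: list[CandidateSpecies], config: SyntheticConfig,
                 path: str | Path) -> list[dict]:
    """Write an MS1 peak-list TSV; return the per-truth planted peaks.

    Each truth appears once at a random charge 1-3, perturbed by Gaussian
    ppm error (sigma = ``ms1_noise_ppm``); decoys are uniform over the
    configured m/z range with unknown charge.
    """
    if not truths:
        raise ValueError("no truths to simulate")
    rng = np.random.default_rng(config.seed + 3)
    rows, planted = [], []
    for cand in truths:
        z = int(rng.integers(1, 4))
        calc = (cand.neutral_mass + z * PROTON) / z
        eps = rng.normal(0.0, config.ms1_noise_ppm)
        obs = calc * (1.0 + eps * 1e-6)
        intensity = float(rng.uniform(1e4, 1e6))
        rows.append((obs, z, intensity))
        planted.append({"species_key": cand.species_key, "charge": z,
                        "calculated_mz": calc, "observed_mz": obs,
                        "ppm": eps})
    lo, hi = config.decoy_mz_range
    for _ in range(config.n_decoys):
        rows.append((float(rng.uniform(lo, hi)), 0,
                     float(rng.uniform(1e3, 1e5))))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("mz\tcharge\tintensity\n")
        for mz_val, z, inten in rows:
            fh.write(f"{mz_val:.6f}\t{z}\t{inten:.1f}\n")
    return planted


def simulate_ms2(truths: list[CandidateSpecies], config: SyntheticConfig,
                 path: str | Path) -> None:
    """Write an MGF with one spectrum per truth that predicts fragments.

    A random subset (default 70%) of the predicted 1+ fragments is emitted
    with Gaussian ppm error, plus uniform noise peaks; precursor fields
    carry the 2+ species m/z.
    """
    rng = np.random.default_rng(config.seed + 4)
    with open(path, "w") as fh:
        for cand in truths:
            frags = [f for f in predict_fragments(cand, charges=(1,))]
            if not frags:
                continue
            n_keep = int(round(config.ms2_fragment_fraction * len(frags)))
            keep = sorted(rng.choice(len(frags), size=n_keep,
                                     replace=False)) if n_keep else []
            mzs = []
            for fi in keep:
                eps = rng.normal(0.0, config.ms2_noise_ppm)
                mzs.append(frags[fi].mz * (1.0 + eps * 1e-6))
            for _ in range(config.ms2_n_noise_peaks):
                mzs.append(float(rng.uniform(100.0, 1500.0)))
            if not mzs:
                continue  # an instrument records no empty spectrum
            mzs.sort()
            prec_mz = (cand.neutral_mass + 2 * PROTON) / 2
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={cand.species_key}\n")
            fh.write(f"PEPMASS={prec_mz:.6f}\n")
            fh.write("CHARGE=2+\n")
            for m in mzs:
                fh.write(f"{m:.6f} {float(rng.uniform(1e3, 1e5)):.1f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# published worked examples, for golden tests and demo runs

#: Worked examples transcribed from the published characterization work.
#: Each entry: core, crosslinks as (i, j, kind), free dehydrations, chain
#: spans after any ring-internal scission, and the printed [M+zH]z+ value.
#: The larlan A2 core is a reconstruction: the printed chain fragments
#: (N-terminal "STCTY", C-terminal "CPTCDF"), the three MeLan rings
#: Thr2-Cys10 / Cys3-Thr9 / Thr4-Cys7 and the printed m/z pin the single
#: unprinted residue to Gly by exact mass.
PAPER_EXAMPLES: dict[str, dict] = {
    "sallan_A2": {
        "core": "CTRYSF",
        "crosslinks": [(1, 5, "Lan")],
        "free_dehydrations": 0,
        "chains": [(1, 6)],
        "charge": 2,
        "printed_mz": 379.6682,
    },
    "sallan_A1": {
        "core": "DCTRYSF",
        "crosslinks": [(2, 6, "Lan")],
        "free_dehydrations": 0,
        "chains": [(1, 7)],
        "charge": 2,
        "printed_mz": 437.1816,
    },
    "larlan_A2": {
        "core": "STCTYGCPTCDF",   # G6 inferred by exact mass (synthetic stand-in)
        "crosslinks": [(2, 10, "MeLan"), (3, 9, "MeLan"), (4, 7, "MeLan")],
        "free_dehydrations": 0,
        "chains": [(1, 5), (6, 12)],  # scission inside the rings at bond 5-6
        "charge": 2,
        "printed_mz": 631.2198,
    },
    "pellan": {
        # two dehydrations among Thr2/Cys4/Ser7/Cys12; intertwined rings
        "core": "STGCYISDKPVCI",
        "crosslinks": [(2, 12, "MeLan"), (4, 7, "Lan")],
        "free_dehydrations": 0,
        "chains": [(1, 13)],
        "charge": 2,
        "printed_mz": None,
    },
    "archalan_gamma": {
        # methylated Cys1, disulfide Cys1-Cys8, rings Ser2-Cys3 and Thr5-Cys9
        "core": "CSCYTRICCDIDS",
        "crosslinks": [(2, 3, "Lan"), (5, 9, "MeLan"), (1, 8, "disulfide")],
        "free_dehydrations": 0,
        "extra_mods": {"methylation": 1},
        "chains": [(1, 13)],
        "charge": 2,
        "printed_mz": None,
    },
}


def example_species(name: str) -> CandidateSpecies:
    """Build the CandidateSpecies for one published worked example."""
    from .enumeration import Crosslink, RingTopology
    spec = PAPER_EXAMPLES[name]
    links = tuple(Crosslink(i, j, kind) for i, j, kind in spec["crosslinks"])
    n_rings = sum(1 for l in links if l.is_thioether)
    n_ss = sum(1 for l in links if l.kind == "disulfide")
    mods = {"thioether_ring": n_rings, "disulfide": n_ss,
            "dehydration": spec["free_dehydrations"]}
    mods.update(spec.get("extra_mods", {}))
    return CandidateSpecies(name, spec["core"], spec["chains"],
                            RingTopology(links), mods,
                            n_scissions=len(spec["chains"]) - 1)


def write_fixtures(outdir: str | Path) -> Path:
    """Write the worked-example cores as FASTA plus an annotation TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "examples.fasta"
    table = outdir / "examples.tsv"
    with open(fasta, "w") as fh:
        for name, spec in PAPER_EXAMPLES.items():
            fh.write(f">{name}\n{spec['core']}\n")
    with open(table, "w") as fh:
        fh.write("name\tcore\ttopology\tn_chains\tneutral_mass\t"
                 "charge\tcalculated_mz\tprinted_mz\n")
        for name, spec in PAPER_EXAMPLES.items():
            cand = example_species(name)
            z = spec["charge"]
            calc = (cand.neutral_mass + z * PROTON) / z
            printed = spec["printed_mz"]
            fh.write(f"{name}\t{spec['core']}\t"
                     f"{cand.topology.to_string(cand.core)}\t"
                     f"{cand.n_chains}\t{cand.neutral_mass:.6f}\t{z}\t"
                     f"{calc:.4f}\t"
                     f"{'' if printed is None else printed}\n")
    return outdir
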