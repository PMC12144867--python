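"""MS1 ppm matching and ring-topology-aware MS/MS fragment prediction.

MS1: every candidate species is protonated at the configured charge states
and matched against a sorted peak list by binary search within a ppm
tolerance (default 10 ppm).

MS/MS: b/y fragment ions are predicted per chain, but a backbone bond
spanned by a thioether or disulfide crosslink cannot release a fragment
pair — the two halves stay covalently attached — so only bonds whose
cleavage actually separates a clean chain prefix (b) or suffix (y) from
the rest of the (possibly multi-chain) species are emitted.  A fragment
that encloses complete rings is lighter by each ring's dehydration
(-18.010565 Da per thioether ring; -2.015650 Da per enclosed disulfide),
reproducing diagnostic ions such as "b5, -H2O, -18 Da" for a ring closed
between residues 1 and 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as pymgf

from .enumeration import CandidateSpecies
from .masses import MOD_DELTAS, PROTON, WATER, ppm_error, residue_mass, round_mz

__all__ = [
    "Peak",
    "PeakList",
    "Ms2Spectrum",
    "FragmentIon",
    "MassMatch",
    "read_peaklist",
    "match_ms1",
    "predict_fragments",
    "match_ms2",
    "annotate_report",
]

logger = logging.getLogger(__name__)


class PeakDataError(ValueError):
    """Unparseable or invalid peak data."""


@dataclass(frozen=True)
class Peak:
    mz: float
    charge: int = 0  # 0 = unknown
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise PeakDataError(f"non-positive m/z {self.mz}")
        if self.intensity < 0:
            raise PeakDataError(f"negative intensity {self.intensity}")


@dataclass
class PeakList:
    """Observed MS1 peaks, kept sorted ascending by m/z."""

    peaks: list[Peak]
    run_id: str = ""

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if mzs != sorted(mzs):
            logger.warning("peak list %s was unsorted; sorting", self.run_id)
            self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)


@dataclass
class Ms2Spectrum:
    """One fragment spectrum with its precursor annotation."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray


@dataclass(frozen=True)
class FragmentIon:
    series: str          # "b" | "y"
    index: int           # residues in the fragment
    chain_index: int     # which chain of the species
    charge: int
    mz: float
    ring_deficit: float  # Da removed by enclosed crosslinks
    annotation: str


@dataclass
class MassMatch:
    species_key: str
    peak: Peak
    charge: int
    calculated_mz: float
    ppm: float           # signed, calculated in the denominator
    neutral_mass: float
    precursor_id: str = ""
    ms2_support: "Ms2Support | None" = None


@dataclass
class Ms2Support:
    n_matched: int
    annotations: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers

def read_peaklist(path: str | Path, format: str = "tsv"
                  ) -> PeakList | list[Ms2Spectrum]:
    """Read MS1 peaks (tsv) or MS2 spectra (mgf, mzml).

    TSV columns: mz, charge, intensity (header optional; charge 0 =
    unknown).  MGF/mzML go through pyteomics; precursor pepmass and charge
    are preserved.
    """
    path = Path(path)
    if format == "tsv":
        peaks = []
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                try:
                    mz = float(parts[0])
                except ValueError:
                    if line_no == 1:
                        continue  # header
                    raise PeakDataError(f"{path}:{line_no}: bad row {line!r}")
                charge = int(float(parts[1])) if len(parts) > 1 else 0
                intensity = float(parts[2]) if len(parts) > 2 else 0.0
                peaks.append(Peak(mz=mz, charge=charge, intensity=intensity))
        if not peaks:
            logger.warning("empty peak list %s", path)
        return PeakList(peaks=peaks, run_id=path.stem)
    if format == "mgf":
        spectra = []
        with pymgf.MGF(str(path)) as reader:
            for k, entry in enumerate(reader):
                params = entry["params"]
                charge = int(params["charge"][0]) if "charge" in params else 0
                spectra.append(Ms2Spectrum(
                    spectrum_id=str(params.get("title", f"scan{k}")),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float)))
        return spectra
    if format == "mzml":
        from pyteomics import mzml as pymzml
        spectra = []
        with pymzml.MzML(str(path)) as reader:
            for entry in reader:
                if entry.get("ms level") != 2:
                    continue
                precursor = entry["precursorList"]["precursor"][0][
                    "selectedIonList"]["selectedIon"][0]
                spectra.append(Ms2Spectrum(
                    spectrum_id=entry.get("id", ""),
                    precursor_mz=float(precursor["selected ion m/z"]),
                    precursor_charge=int(precursor.get("charge state", 0)),
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float)))
        return spectra
    raise PeakDataError(f"unknown peak list format {format!r}")


# ---------------------------------------------------------------------------
# MS1

def match_ms1(library: list[CandidateSpecies], peaklist: PeakList,
              tol_ppm: float = 10.0, charges: tuple[int, ...] = (1, 2, 3)
              ) -> list[MassMatch]:
    """Match the candidate library against an MS1 peak list.

    Every species x allowed charge is searched against the sorted peaks by
    binary search within ``tol_ppm``.  Peaks with a declared charge are
    only matched at that charge; unknown-charge peaks (0) at any.  Matches
    are returned sorted by |ppm| (then species key, for determinism).
    """
    if tol_ppm <= 0:
        raise PeakDataError("tol_ppm must be positive")
    if not library or not len(peaklist):
        return []
    peak_mz = peaklist.mz_array
    masses = np.array([c.neutral_mass for c in library], dtype=float)
    matches: list[MassMatch] = []
    for z in charges:
        calc = (masses + z * PROTON) / z
        tol = calc * tol_ppm * 1e-6
        lo = np.searchsorted(peak_mz, calc - tol, side="left")
        hi = np.searchsorted(peak_mz, calc + tol, side="right")
        for ci in np.nonzero(hi > lo)[0]:
            cand = library[ci]
            for peak in peaklist.peaks[lo[ci]:hi[ci]]:
                if peak.charge not in (0, z):
                    continue
                matches.append(MassMatch(
                    species_key=cand.species_key, peak=peak, charge=z,
                    calculated_mz=float(calc[ci]),
                    ppm=ppm_error(peak.mz, float(calc[ci]), signed=True),
                    neutral_mass=cand.neutral_mass,
                    precursor_id=cand.precursor_id))
    matches.sort(key=lambda m: (abs(m.ppm), m.species_key, m.charge))
    return matches


# ---------------------------------------------------------------------------
# MS/MS

def _link_delta(kind: str) -> float:
    return MOD_DELTAS["thioether_ring"] if kind != "disulfide" \
        else MOD_DELTAS["disulfide"]


def predict_fragments(candidate: CandidateSpecies,
                      charges: tuple[int, ...] = (1, 2)) -> list[FragmentIon]:
    """Predict b/y ions allowed by the species' ring topology.

    For each backbone bond of each chain the cleavage is tested by the
    crosslink-span rule (equivalent to brute-force connectivity): a b ion
    at bond k of a chain exists iff no crosslink has exactly one endpoint
    in the chain prefix 1..k — otherwise the prefix remains covalently
    attached.  Enclosed crosslinks subtract their deltas from the fragment
    mass.  Fragment masses place ring dehydrations at their rings;
    unpositioned free dehydrations and tailoring modifications are not
    distributed onto fragments.
    """
    fragments: list[FragmentIon] = []
    links = candidate.topology.crosslinks
    for ci, (a, b) in enumerate(candidate.chains):
        seq = candidate.core[a - 1: b]
        n = len(seq)
        prefix_mass = np.cumsum([residue_mass(c) for c in seq])
        total = prefix_mass[-1]
        for k in range(1, n):
            prefix = range(a, a + k)          # core positions of b_k
            suffix = range(a + k, b + 1)      # core positions of y_{n-k}
            for series, span in (("b", prefix), ("y", suffix)):
                span_set = set(span)
                inside = [l for l in links
                          if l.i in span_set and l.j in span_set]
                straddle = any((l.i in span_set) != (l.j in span_set)
                               for l in links)
                if straddle:
                    continue
                deficit = sum(_link_delta(l.kind) for l in inside)
                if series == "b":
                    neutral = float(prefix_mass[k - 1]) + deficit
                    index = k
                else:
                    neutral = float(total - prefix_mass[k - 1]) + WATER + deficit
                    index = n - k
                ann = f"{series}{index}"
                n_rings = sum(1 for l in inside if l.kind != "disulfide")
                if n_rings == 1:
                    ann += ", -H2O, -18 Da"
                elif n_rings > 1:
                    ann += f", -{n_rings}H2O, -{18 * n_rings} Da"
                for z in charges:
                    fragments.append(FragmentIon(
                        series=series, index=index, chain_index=ci,
                        charge=z, mz=(neutral + z * PROTON) / z,
                        ring_deficit=deficit,
                        annotation=ann if z == 1 else f"{ann} ({z}+)"))
    fragments.sort(key=lambda f: (f.chain_index, f.series, f.index, f.charge))
    return fragments


def match_ms2(candidate: CandidateSpecies, spectrum: Ms2Spectrum,
              tol_ppm: float = 20.0,
              charges: tuple[int, ...] = (1, 2)) -> Ms2Support:
    """Greedy nearest-peak assignment of predicted fragments.

    All (fragment, peak) pairs within ``tol_ppm`` are ranked by |ppm| and
    assigned greedily, each observed peak and each predicted fragment used
    at most once.
    """
    predicted = predict_fragments(candidate, charges=charges)
    if not predicted or spectrum.mz.size == 0:
        return Ms2Support(n_matched=0)
    pairs = []
    for fi, frag in enumerate(predicted):
        dev = np.abs(spectrum.mz - frag.mz) / frag.mz * 1e6
        for pi in np.nonzero(dev <= tol_ppm)[0]:
            pairs.append((float(dev[pi]), fi, int(pi)))
    pairs.sort()
    used_f: set[int] = set()
    used_p: set[int] = set()
    annotations = []
    for _, fi, pi in pairs:
        if fi in used_f or pi in used_p:
            continue
        used_f.add(fi)
        used_p.add(pi)
        annotations.append(predicted[fi].annotation)
    return Ms2Support(n_matched=len(annotations), annotations=annotations)


# ---------------------------------------------------------------------------
# reporting

def annotate_report(matches: list[MassMatch]) -> pd.DataFrame:
    """Tabulate matches in the field's reporting style.

    Columns include observed/calculated m/z at 4 decimals and |Δ| ppm at
    1 decimal (e.g. "observed 379.6688 / calculated 379.6682", Δ "1.6"),
    plus fragment-evidence annotations when MS2 support was attached.
    """
    rows = []
    for m in matches:
        support = m.ms2_support
        rows.append({
            "species_key": m.species_key,
            "precursor_id": m.precursor_id,
            "charge": m.charge,
            "observed_mz": round_mz(m.peak.mz),
            "calculated_mz": round_mz(m.calculated_mz),
            "delta_ppm": f"{abs(m.ppm):.1f}",
            "signed_ppm": m.ppm,
            "neutral_mass": m.neutral_mass,
            "intensity": m.peak.intensity,
            "n_fragments": 0 if support is None else support.n_matched,
            "fragment_evidence": "" if support is None
            else "; ".join(support.annotations),
        })
    columns = ["species_key", "precursor_id", "charge", "observed_mz",
               "calculated_mz", "delta_ppm", "signed_ppm", "neutral_mass",
               "intensity", "n_fragments", "fragment_evidence"]
    return pd.DataFrame(rows, columns=columns)


def write_report(matches: list[MassMatch], path: str | Path) -> None:
    annotate_report(matches).to_csv(path, sep="\t", index=False)
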