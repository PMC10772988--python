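"""Desk-scale synthetic kinetics data with Arrhenius temperature dependence,
plus a toy metabolic-model fixture for proteome-constrained FBA.

Each simulated compound-protein pair carries a ground-truth pre-exponential
amplitude log10(A) and activation energy Ea, and its turnover number obeys

    kcat(T) = 10^{log10(A)} * exp(-Ea / (R T)) * 10^eps,   eps ~ N(0, sigma)

measured at several temperatures (in degrees Celsius in the emitted table).
So that sequence and structure carry learnable signal, log10(A) is a linear
function of the counts of three designated 3-mer motifs inserted into the
protein sequence, and Ea is tied to the substrate's oxygen count -- a
deliberately simple coupling that makes parameter recovery a meaningful
test for the encoders, not a claim about real enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .featurize import KELVIN_OFFSET, STANDARD_RESIDUES, apply_mutations
from .proteome_fba import (EnzymeAssignment, MetabolicModel,
                           ProteomeSectorSpec, Reaction)
from .train import KineticsEntry

GAS_CONSTANT = 8.314  # J/(mol K)
LN10 = np.log(10.0)

#: small-molecule SMILES templates; linear-safe (can be prefixed with an
#: alkyl chain and stay valid)
SMILES_TEMPLATES = [
    "CO", "CCO", "CC(=O)O", "CC(N)C(=O)O", "C(C(=O)O)O", "C1CCCCC1",
    "c1ccccc1", "c1ccccc1O", "c1ccc(cc1)C(=O)O", "CC(=O)C(=O)O",
    "C(CO)O", "C(C(C(=O)O)O)O", "OCC(O)C(O)C(O)C(O)CO", "CC(O)C(=O)O",
    "NCC(=O)O", "CCC(=O)O", "CCCC(=O)O", "CCCCC(=O)O", "CC(C)C(=O)O",
    "C1CCOC1", "C1CCNC1", "c1ccncc1", "c1ccoc1", "c1ccsc1",
    "CC(=O)N", "CCN", "CCCN", "OC(=O)CCC(=O)O", "OC(=O)CC(=O)O",
    "OC(=O)C=CC(=O)O", "CC(O)CO", "OCC1OC(O)C(O)C(O)C1O",
    "NC(=O)C1CCCN1", "CSCCC(N)C(=O)O", "NC(CS)C(=O)O", "NC(CO)C(=O)O",
    "CC(C)CC(N)C(=O)O", "NC(Cc1ccccc1)C(=O)O", "OC(=O)c1ccccc1O",
    "COC(=O)c1ccccc1", "CN1CCCC1", "OCCN", "OCCO", "OCCCO",
    "CC(=O)OC", "CCOC(=O)C", "CC#N", "CC=O", "OC=O", "C(=O)(O)O",
]

MOTIFS = ("AKR", "WND", "CYH")   # sequence 3-mers whose counts set log10(A)


@dataclass
class ArrheniusSpec:
    """Generator settings; defaults emulate a sparse, mid-T-heavy kinetics set."""

    n_pairs: int = 60
    temps_C: tuple[float, ...] = (10.0, 20.0, 25.0, 30.0, 37.0, 50.0)
    logA_range: tuple[float, float] = (6.0, 12.0)     # log10(1/s)
    Ea_range: tuple[float, float] = (20e3, 80e3)      # J/mol
    noise_sigma: float = 0.1                          # log10 units
    seq_len_range: tuple[int, int] = (50, 300)
    skew_temperatures: bool = False
    R: float = GAS_CONSTANT
    seed: int = 0

    def __post_init__(self):
        if not self.temps_C:
            raise ValueError("temps_C must be non-empty")
        for lo, hi in (self.logA_range, self.Ea_range, self.seq_len_range):
            if lo > hi:
                raise ValueError("ranges must be ordered (lo <= hi)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticDataset:
    entries: list[KineticsEntry]
    truth: pd.DataFrame    # pair_id, smiles, sequence, logA, Ea, mutation info


def arrhenius_log10_kcat(logA: float, Ea: float, t_celsius: float,
                         R: float = GAS_CONSTANT) -> float:
    """Noise-free log10 kcat of the Arrhenius law at temperature T (C)."""
    t_k = t_celsius + KELVIN_OFFSET
    return logA - Ea / (R * t_k * LN10)


def _random_smiles(rng: np.random.Generator) -> str:
    base = SMILES_TEMPLATES[rng.integers(len(SMILES_TEMPLATES))]
    decorated = "C" * int(rng.integers(0, 4)) + base
    if Chem.MolFromSmiles(decorated) is None:   # decoration broke valence
        decorated = base
    return decorated


def _random_sequence(rng: np.random.Generator, length: int,
                     motif_counts: tuple[int, int, int]) -> str:
    residues = sorted(STANDARD_RESIDUES)
    seq = list(rng.choice(residues, size=length))
    # plant the designated motifs at non-overlapping random positions
    slots = list(range(0, length - 3, 3))
    rng.shuffle(slots)
    k = 0
    for motif, count in zip(MOTIFS, motif_counts):
        for _ in range(count):
            if k >= len(slots):
                break
            pos = slots[k]
            seq[pos:pos + 3] = motif
            k += 1
    return "".join(seq)


def _ea_from_smiles(smiles: str, ea_range: tuple[float, float]) -> float:
    """Ea tied to the substrate's oxygen count (a proxy 'substructure')."""
    mol = Chem.MolFromSmiles(smiles)
    n_ox = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "O")
    lo, hi = ea_range
    return lo + (hi - lo) * min(n_ox, 6) / 6.0


def generate_arrhenius_dataset(spec: ArrheniusSpec) -> SyntheticDataset:
    """Generate the synthetic kinetics table plus its ground-truth parameters."""
    rng = np.random.default_rng(spec.seed)
    entries: list[KineticsEntry] = []
    truth_rows = []
    seen_pairs: set[tuple[str, str]] = set()
    temps = np.asarray(spec.temps_C, dtype=float)
    if spec.skew_temperatures:
        weights = np.where((temps >= 20.0) & (temps <= 40.0), 4.0, 1.0)
        weights = weights / weights.sum()
    for pid in range(spec.n_pairs):
        for _ in range(100):
            smiles = _random_smiles(rng)
            motif_counts = tuple(int(c) for c in rng.integers(0, 5, size=3))
            length = int(rng.integers(spec.seq_len_range[0],
                                      spec.seq_len_range[1] + 1))
            sequence = _random_sequence(rng, length, motif_counts)
            if (smiles, sequence) not in seen_pairs:
                seen_pairs.add((smiles, sequence))
                break
        lo, hi = spec.logA_range
        logA = lo + (hi - lo) * sum(motif_counts) / 12.0 \
            + rng.normal(0.0, 0.02 * (hi - lo))
        logA = float(np.clip(logA, lo, hi))
        ea = _ea_from_smiles(smiles, spec.Ea_range)
        if spec.skew_temperatures:
            pair_temps = rng.choice(temps, size=len(temps), p=weights)
        else:
            pair_temps = temps
        for t in pair_temps:
            eps = rng.normal(0.0, spec.noise_sigma) if spec.noise_sigma > 0 else 0.0
            log_k = arrhenius_log10_kcat(logA, ea, float(t), spec.R) + eps
            entries.append(KineticsEntry(smiles=smiles, sequence=sequence,
                                         temperature_C=float(t),
                                         kcat=float(10.0 ** log_k)))
        truth_rows.append({"pair_id": pid, "smiles": smiles, "sequence": sequence,
                           "logA": logA, "Ea": ea, "mutation": None,
                           "parent_pair_id": None})
    return SyntheticDataset(entries=entries, truth=pd.DataFrame(truth_rows))


def inject_mutation_effects(dataset: SyntheticDataset, n_mutants: int,
                            effect_range: float, seed: int = 0) -> SyntheticDataset:
    """Add point-mutated variants of existing pairs with shifted log10(A).

    Each mutant derives from a distinct wild-type pair; its true log10(A) is
    shifted by a uniform draw in [-effect_range, +effect_range] and its
    entries regenerated at the same temperatures.  Mutated positions are
    recorded as ground truth.
    """
    wt = dataset.truth[dataset.truth.mutation.isna()]
    if n_mutants > len(wt):
        raise ValueError(f"cannot create {n_mutants} mutants from {len(wt)} pairs")
    rng = np.random.default_rng(seed)
    picked = rng.choice(wt.index.values, size=n_mutants, replace=False)
    entries = list(dataset.entries)
    truth = dataset.truth.copy()
    by_pair: dict[str, list[KineticsEntry]] = {}
    for e in dataset.entries:
        by_pair.setdefault(e.sequence, []).append(e)
    residues = sorted(STANDARD_RESIDUES)
    next_id = int(truth.pair_id.max()) + 1
    new_rows = []
    for idx in picked:
        row = truth.loc[idx]
        seq = row.sequence
        n_sites = int(rng.integers(1, 4))
        positions = rng.choice(len(seq), size=n_sites, replace=False) + 1
        specs = []
        for pos in sorted(positions):
            ref = seq[pos - 1]
            alt = ref
            while alt == ref:
                alt = residues[rng.integers(len(residues))]
            specs.append(f"{ref}{pos}{alt}")
        spec_str = "/".join(specs)
        mut_seq = apply_mutations(seq, spec_str)
        effect = float(rng.uniform(-effect_range, effect_range)) if effect_range > 0 else 0.0
        mut_logA = row.logA + effect
        sigma_entries = by_pair[seq]
        noise = 0.0
        for e in sigma_entries:
            # recover this entry's noise so effect_range=0 reproduces WT kcat
            base = arrhenius_log10_kcat(row.logA, row.Ea, e.temperature_C)
            noise = np.log10(e.kcat) - base
            log_k = arrhenius_log10_kcat(mut_logA, row.Ea, e.temperature_C) + noise
            entries.append(KineticsEntry(smiles=e.smiles, sequence=mut_seq,
                                         temperature_C=e.temperature_C,
                                         kcat=float(10.0 ** log_k)))
        new_rows.append({"pair_id": next_id, "smiles": row.smiles,
                         "sequence": mut_seq, "logA": mut_logA, "Ea": row.Ea,
                         "mutation": spec_str, "parent_pair_id": int(row.pair_id)})
        next_id += 1
    truth = pd.concat([truth, pd.DataFrame(new_rows)], ignore_index=True)
    return SyntheticDataset(entries=entries, truth=truth)


def generate_toy_gsmm(seed: int = 0):
    """A hand-computable ~7-reaction toy metabolic model with sector data.

    Pathway: glucose uptake (CT) -> hexokinase-like step -> glycolysis lump
    producing 2 pyruvate -> growth (2 pyr -> biomass + acetate byproduct)
    with acetate export (AT); an optional pyr -> ac overflow branch.  The
    sector-constrained optimum has a closed form recorded alongside:
    growth* = min(uptake_ub, budget / c) with c the summed mass-per-flux
    coefficient along the active route.

    Returns (model, sectors, expected) where expected maps scenario name to
    the hand-derived optimum.
    """
    rng = np.random.default_rng(seed)
    uptake_ub = 100.0
    k_hex, mw_hex = float(rng.uniform(80, 120)), 50000.0
    k_gly, mw_gly = float(rng.uniform(40, 60)), 60000.0
    a_pfl = 30.0   # umol/min/mg
    model = MetabolicModel(
        metabolites=["glc", "g6p", "pyr", "ac", "biomass"],
        reactions=[
            Reaction("EX_glc", {"glc": 1.0}, 0.0, uptake_ub),
            Reaction("HEX", {"glc": -1.0, "g6p": 1.0}, 0.0, 1000.0),
            Reaction("GLY", {"g6p": -1.0, "pyr": 2.0}, 0.0, 1000.0),
            Reaction("PFL", {"pyr": -1.0, "ac": 1.0}, 0.0, 1000.0),
            Reaction("GROWTH", {"pyr": -2.0, "ac": 1.0, "biomass": 1.0}, 0.0, 1000.0),
            Reaction("EX_ac", {"ac": -1.0}, 0.0, 1000.0),
            Reaction("EX_biomass", {"biomass": -1.0}, 0.0, 1000.0),
        ],
        objective_reaction="GROWTH",
    )
    sectors = ProteomeSectorSpec(
        phi_Q=0.5, P_TOT=0.5, a_ribosome=107.4, a_AT=6360.0, a_CT=361.14,
        transport_reactions={"EX_glc": "CT", "EX_ac": "AT"},
        catabolic={
            "HEX": EnzymeAssignment("HEX", "turnover", k_cat=k_hex, MW=mw_hex),
            "GLY": EnzymeAssignment("GLY", "turnover", k_cat=k_gly, MW=mw_gly),
            "PFL": EnzymeAssignment("PFL", "specific_activity", a=a_pfl),
        },
    )
    # active route per unit growth: EX_glc=HEX=GLY=1, GROWTH=1, EX_ac=1, PFL=0
    c = (1.0 / sectors.a_ribosome
         + (mw_hex / 1000.0) / (k_hex * 3600.0)
         + (mw_gly / 1000.0) / (k_gly * 3600.0)
         + 1.0 / sectors.a_CT
         + 1.0 / sectors.a_AT)
    expected = {
        "plain_fba_growth": uptake_ub,                     # uptake-limited
        "constrained_growth": min(uptake_ub, sectors.budget / c),
        "mass_per_growth": c,
    }
    return model, sectors, expected
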