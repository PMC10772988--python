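"""Interpretation of residue attention weights and mutant-enzyme scans.

The residue-to-atom attention vector alpha_r2a of the trained model assigns
each protein 3-mer a weight; mapped to the window's center residue this
gives a per-residue importance profile.  Mutation sites with a strong kcat
penalty (< 0.1-fold wild type) tend to lie near profile peaks, and scanning
candidate substitutions predicts their effect on kcat across temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featurize import apply_mutations
from .model import KcatModel

SEVERE_FOLD_CHANGE = 0.1   # mutants below 0.1-fold WT kcat count as severe


@dataclass
class ResidueAttentionProfile:
    """Per-head and head-averaged residue attention weights.

    Window j (0-based) maps to its center residue, 1-based position j+2;
    each head's weights form a probability simplex over windows.
    """

    per_head: np.ndarray          # (heads, N_r)
    mean_profile: np.ndarray      # (N_r,)
    residue_positions: np.ndarray  # (N_r,) 1-based center positions

    @property
    def n_windows(self) -> int:
        return self.mean_profile.shape[0]


@dataclass
class MutationAnnotation:
    position: int          # 1-based residue index
    fold_change: float     # mutant kcat / WT kcat

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if not self.fold_change > 0:
            raise ValueError("fold_change must be positive")

    @property
    def severe(self) -> bool:
        return self.fold_change < SEVERE_FOLD_CHANGE


@dataclass
class MutationReport:
    table: pd.DataFrame
    peaks: list[int]                      # 1-based residue positions of maxima
    fraction_severe_near_peak: float      # NaN when no severe mutations/peaks
    window: int


def residue_attention(model: KcatModel, smiles: str, sequence: str,
                      t_celsius: float) -> ResidueAttentionProfile:
    """Extract alpha_r2a from the forward pass for one enzyme-substrate-T.

    The weights are exactly those computed inside the bidirectional
    attention block (shared code path, no re-derivation).
    """
    att = model.attention_single(smiles, sequence, t_celsius)
    per_head = att.alpha_r2a[:, 0, :]                 # (heads, N_r)
    mean = per_head.mean(axis=0)
    positions = np.arange(per_head.shape[1]) + 2     # center of window j
    return ResidueAttentionProfile(per_head=per_head, mean_profile=mean,
                                   residue_positions=positions)


def find_profile_peaks(values: np.ndarray) -> list[int]:
    """Indices (0-based) of strict local maxima of `values`.

    A plateau counts once, at its leftmost point, and only when both flanking
    values are strictly smaller; a plateau spanning the whole vector (e.g. a
    uniform profile) yields no peak.  Peaks depend on ordering only, so the
    result is invariant to uniform scaling of the profile.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        full_span = i == 0 and j == n - 1
        if left_ok and right_ok and not full_span:
            peaks.append(i)
        i = j + 1
    return peaks


def annotate_mutations(profile: ResidueAttentionProfile,
                       annotations: list[MutationAnnotation],
                       window: int = 10) -> MutationReport:
    """Relate mutation sites to peaks of the mean attention profile.

    For each mutation: the distance (in residues) to the nearest local
    maximum (ties resolve to the lower position).  The summary is the
    fraction of severe mutations (< 0.1-fold WT kcat) within `window`
    residues of a peak.
    """
    peak_idx = find_profile_peaks(profile.mean_profile)
    peak_pos = [int(profile.residue_positions[i]) for i in peak_idx]
    rows = []
    for ann in annotations:
        if peak_pos:
            dists = [abs(ann.position - p) for p in peak_pos]
            dmin = min(dists)
            nearest = min(p for p, dd in zip(peak_pos, dists) if dd == dmin)
        else:
            dmin, nearest = math.nan, None
        rows.append({"position": ann.position, "fold_change": ann.fold_change,
                     "severe": ann.severe, "nearest_peak": nearest,
                     "distance": dmin})
    table = pd.DataFrame(rows, columns=["position", "fold_change", "severe",
                                        "nearest_peak", "distance"])
    severe = table[table.severe] if len(table) else table
    if len(severe) and peak_pos:
        frac = float((severe.distance <= window).mean())
    else:
        frac = math.nan
    return MutationReport(table=table, peaks=peak_pos,
                          fraction_severe_near_peak=frac, window=window)


def mutant_scan(model: KcatModel, wild_type: str, specs: list[str],
                substrate: str, temps_celsius: list[float]) -> pd.DataFrame:
    """Predict log10(kcat) for the wild type and each mutation spec at each
    temperature; fold changes are relative to the wild type at the same T.

    Columns: variant, mutation, temperature_C, log10_kcat, fold_change_vs_wt.
    The wild-type rows have fold change exactly 1.
    """
    variants = [("WT", None, wild_type)]
    for spec in specs:
        variants.append((spec, spec, apply_mutations(wild_type, spec)))
    rows = [(substrate, seq, t) for _, _, seq in variants for t in temps_celsius]
    preds = model.predict(rows)
    nt = len(temps_celsius)
    wt_preds = preds[:nt]
    out = []
    for vi, (name, spec, _seq) in enumerate(variants):
        for ti, t in enumerate(temps_celsius):
            p = preds[vi * nt + ti]
            fold = 1.0 if vi == 0 else float(10.0 ** (p - wt_preds[ti]))
            out.append({"variant": name, "mutation": spec, "temperature_C": t,
                        "log10_kcat": float(p), "fold_change_vs_wt": fold})
    return pd.DataFrame(out)


def profile_to_frame(profile: ResidueAttentionProfile) -> pd.DataFrame:
    """CSV-ready view: position, head1..headH, mean."""
    data = {"position": profile.residue_positions}
    for h in range(profile.per_head.shape[0]):
        data[f"head{h + 1}"] = profile.per_head[h]
    data["mean"] = profile.mean_profile
    return pd.DataFrame(data)
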