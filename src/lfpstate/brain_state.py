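"""Global brain-state description by concatenated fractal-normalized spectra.

A condition's global state is fingerprinted by concatenating the
time-averaged oscillatory_db spectra (1-300 Hz) of the declared structures,
in a fixed recorded order.  States are compared by Pearson correlation of
these vectors; treatments are placed relative to the baseline and
psychotomimetic-plus-vehicle states by per-animal correlation coefficients,
compared across groups with rank-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from .stats import rank_sum_test, kruskal_wallis


@dataclass
class StateVector:
    """Concatenated per-structure oscillatory_db spectra for one condition."""

    values: np.ndarray
    structures: list[str]         # concatenation order (recorded contract)
    freqs: np.ndarray             # per-structure grid (1-300 Hz)
    animal: str = ""
    session: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.structures) * len(self.freqs):
            raise ValueError("vector length != n_structures * n_freq_bins")


def build_state_vector(structure_spectra: dict[str, np.ndarray],
                       freqs: np.ndarray,
                       structure_list: list[str],
                       f_lo: float = 1.0, f_hi: float = 300.0,
                       **meta: str) -> StateVector:
    """Concatenate per-structure mean oscillatory_db spectra over 1-300 Hz."""
    missing = [s for s in structure_list if s not in structure_spectra]
    if missing:
        raise KeyError(f"missing structures: {missing}")
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    parts = [np.asarray(structure_spectra[s], float)[sel] for s in structure_list]
    return StateVector(values=np.concatenate(parts),
                       structures=list(structure_list), freqs=freqs[sel], **meta)


def correlate_states(v1: StateVector, v2: StateVector) -> float:
    """Pearson correlation between two state vectors (order-checked)."""
    if v1.structures != v2.structures:
        raise ValueError("structure order differs between vectors")
    if len(v1.values) != len(v2.values):
        raise ValueError("vector lengths differ")
    if np.std(v1.values) == 0 or np.std(v2.values) == 0:
        raise ValueError("zero-variance state vector; correlation undefined")
    if np.array_equal(v1.values, v2.values):
        return 1.0        # exact self-similarity, no floating-point residue
    return float(np.corrcoef(v1.values, v2.values)[0, 1])


def state_similarity_analysis(treatment_vectors: dict[str, list[StateVector]],
                              baseline_vectors: dict[str, StateVector],
                              vehicle_vectors: dict[str, StateVector],
                              min_group: int = 3) -> dict:
    """Per-animal correlations of each treatment vs baseline and vs vehicle.

    ``treatment_vectors`` maps treatment label -> list of per-animal state
    vectors; ``baseline_vectors`` / ``vehicle_vectors`` map animal -> state
    vector.  Returns per-animal coefficient tables, group medians with
    quartiles, and rank-sum tests between treatments (suppressed below
    ``min_group`` animals per group).
    """
    rows = []
    for treatment, vectors in treatment_vectors.items():
        for v in vectors:
            entry = {"treatment": treatment, "animal": v.animal}
            if v.animal in baseline_vectors:
                entry["r_baseline"] = correlate_states(v, baseline_vectors[v.animal])
            if v.animal in vehicle_vectors:
                entry["r_vehicle"] = correlate_states(v, vehicle_vectors[v.animal])
            rows.append(entry)
    coeffs = pd.DataFrame(rows)
    summary = coeffs.groupby("treatment").agg(
        median_r_baseline=("r_baseline", "median"),
        q25_r_baseline=("r_baseline", lambda s: s.quantile(0.25)),
        q75_r_baseline=("r_baseline", lambda s: s.quantile(0.75)),
        median_r_vehicle=("r_vehicle", "median"),
        q25_r_vehicle=("r_vehicle", lambda s: s.quantile(0.25)),
        q75_r_vehicle=("r_vehicle", lambda s: s.quantile(0.75)),
        n=("animal", "nunique"))
    tests = []
    treatments = sorted(treatment_vectors)
    for i, ta in enumerate(treatments):
        for tb in treatments[i + 1:]:
            for axis in ("r_baseline", "r_vehicle"):
                a = coeffs.loc[coeffs["treatment"] == ta, axis].dropna()
                b = coeffs.loc[coeffs["treatment"] == tb, axis].dropna()
                if len(a) < min_group or len(b) < min_group:
                    continue
                if a.nunique() <= 1 and b.nunique() <= 1 and set(a) == set(b):
                    continue            # degenerate: identical constants
                res = rank_sum_test(a.to_numpy(), b.to_numpy())
                tests.append({"treatment_a": ta, "treatment_b": tb,
                              "axis": axis, "p": res.p,
                              "estimate": res.estimate})
    return {"coefficients": coeffs, "summary": summary,
            "tests": pd.DataFrame(tests)}


def pairwise_treatment_similarity(reference_vectors: list[StateVector],
                                  other_treatments: dict[str, list[StateVector]],
                                  ) -> dict:
    """Reference-vs-other pairwise coefficients with a Kruskal-Wallis omnibus.

    Matches by animal when possible, otherwise pools all cross pairs.
    """
    groups: dict[str, np.ndarray] = {}
    for label, vectors in other_treatments.items():
        by_animal = {v.animal: v for v in vectors}
        rs = []
        for ref in reference_vectors:
            if ref.animal in by_animal:
                rs.append(correlate_states(ref, by_animal[ref.animal]))
            else:
                rs.extend(correlate_states(ref, v) for v in vectors)
        groups[label] = np.asarray(rs, float)
    out: dict = {"coefficients": groups}
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups.values()):
        res = kruskal_wallis(list(groups.values()))
        out["kruskal_wallis_h"] = res.estimate
        out["kruskal_wallis_p"] = res.p
    return out


def quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median with 25th/75th percentiles, the reporting convention used."""
    return tuple(np.percentile(values, [50, 25, 75]))  # type: ignore[return-value]
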