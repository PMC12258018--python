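"""Candidate four-point measurements and sensitivity-guided pattern selection.

A measurement frame is an ordered list of injection/measurement electrode-pair
combinations (the I-M pattern).  Candidates are enumerated from a configurable
electrode-pair ruleset, deduplicated under reciprocity, and the final pattern
is picked by three criteria computed on the sensitivity matrix J:

* greedy Gram-determinant (parallelotope-volume) maximization, favouring long
  and mutually orthogonal sensitivity rows;
* the largest L1 row norms;
* the largest L2 row norms.

The default split (144 volume + 32 L1 + 32 L2 = 208 measurements) mirrors the
common frame size of multi-electrode impedance studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .forward import IMPattern, Measurement
from .geometry import N_SPOKES

DEFAULT_COUNTS = {"volume": 144, "l1": 32, "l2": 32}

INTRA = "intra"
INTER = "inter"


def _pair_class(pair: tuple[int, int]) -> str:
    return INTRA if (pair[0] // N_SPOKES) == (pair[1] // N_SPOKES) else INTER


def electrode_pairs(ruleset: str = "default") -> list[tuple[int, int]]:
    """Electrode pairs eligible for injecting and measuring.

    ``default``: all intra-plane pairs on each plane plus inter-plane pairs
    between spoke-aligned and spoke-adjacent electrodes (the pair set depends
    only on plane/spoke labels, so a pattern transfers between arrays).
    ``all``: every pair of the 16 electrodes.
    """
    if ruleset == "all":
        return list(combinations(range(16), 2))
    if ruleset != "default":
        raise ValueError(f"unknown ruleset {ruleset!r}")
    pairs: list[tuple[int, int]] = []
    for plane in (0, 1):
        base = plane * N_SPOKES
        pairs.extend(
            (base + i, base + j) for i, j in combinations(range(N_SPOKES), 2)
        )
    for k in range(N_SPOKES):
        for dk in (0, 1, N_SPOKES - 1):  # aligned and adjacent spokes
            pairs.append((k, N_SPOKES + ((k + dk) % N_SPOKES)))
    return pairs


@dataclass
class CandidateSet:
    """Reciprocity-unique four-point candidates built from an electrode-pair set."""

    pairs: list[tuple[int, int]]
    measurements: list[Measurement]
    classes: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.measurements)

    def pattern(self, indices) -> IMPattern:
        return IMPattern([self.measurements[i] for i in indices])


def enumerate_candidates(
    ruleset: str = "default",
    pairs: list[tuple[int, int]] | None = None,
) -> CandidateSet:
    """All reciprocity-unique four-point combinations of the eligible pairs.

    Each unordered combination of two disjoint pairs yields exactly one
    candidate (the lower-indexed pair injects), so reciprocity twins are
    excluded by construction.  Deterministic.
    """
    pairs = electrode_pairs(ruleset) if pairs is None else list(pairs)
    meas: list[Measurement] = []
    classes: list[tuple[str, str]] = []
    for ip, mp in combinations(pairs, 2):
        if set(ip) & set(mp):
            continue
        meas.append(Measurement(inject=ip, measure=mp))
        classes.append((_pair_class(ip), _pair_class(mp)))
    return CandidateSet(pairs=pairs, measurements=meas, classes=classes)


def score_l1(J: np.ndarray, meas: int | None = None) -> np.ndarray | float:
    """Sum of absolute sensitivities of a row (or of all rows)."""
    scores = np.abs(J).sum(axis=-1)
    return scores if meas is None else float(np.atleast_1d(scores)[meas])


def score_l2(J: np.ndarray, meas: int | None = None) -> np.ndarray | float:
    """Euclidean norm of a sensitivity row (or of all rows)."""
    scores = np.sqrt((np.asarray(J) ** 2).sum(axis=-1))
    return scores if meas is None else float(np.atleast_1d(scores)[meas])


def gram_volume(J_subset: np.ndarray) -> float:
    """det(J J^T) of the selected rows: the squared parallelotope volume.

    Zero when the rows are linearly dependent; monotone in the geometric
    volume, so rankings are unaffected by the missing square root.
    """
    J_subset = np.atleast_2d(np.asarray(J_subset, dtype=float))
    if J_subset.shape[0] > J_subset.shape[1]:
        raise ValueError("more rows than columns: volume is identically zero")
    return float(np.linalg.det(J_subset @ J_subset.T))


def greedy_gram_select(
    J: np.ndarray, k: int, candidates: np.ndarray | None = None
) -> tuple[list[int], np.ndarray]:
    """Greedy Gram-volume maximization over rows of ``J``.

    Each step adds the candidate whose orthogonal component w.r.t. the span
    of the current selection is largest (the rank-one update of the Gram
    determinant); ties break on the lowest candidate index.  Returns the
    selected indices in pick order and the sequence of squared-norm gains
    (their product is the final Gram determinant).
    """
    J = np.asarray(J, dtype=float)
    idx = np.arange(J.shape[0]) if candidates is None else np.asarray(candidates)
    if k > len(idx):
        raise ValueError(f"cannot select {k} of {len(idx)} candidates")
    rows = np.ascontiguousarray(J[idx])
    resid2 = (rows**2).sum(axis=1)
    chosen: list[int] = []
    gains = np.empty(k)
    chosen_mask = np.zeros(len(idx), dtype=bool)
    # Gram-Schmidt kept in coefficient form: coef[c, t] is the projection of
    # candidate c onto the t-th orthonormal basis vector, so each step costs
    # one matvec against the original rows instead of a full matrix update.
    coef = np.empty((len(idx), k))
    for step in range(k):
        masked = np.where(chosen_mask, -np.inf, resid2)
        pick = int(np.argmax(masked))          # argmax returns the first max
        gains[step] = max(resid2[pick], 0.0)
        chosen.append(int(idx[pick]))
        chosen_mask[pick] = True
        if gains[step] > 0:
            dots = rows @ rows[pick]
            if step:
                dots -= coef[:, :step] @ coef[pick, :step]
            proj = dots / np.sqrt(gains[step])
            coef[:, step] = proj
            resid2 = np.maximum(resid2 - proj**2, 0.0)
        else:
            coef[:, step] = 0.0
    return chosen, gains


def select_pattern(
    J_all: np.ndarray,
    candidates: CandidateSet,
    counts: dict[str, int] | None = None,
    v_ref: np.ndarray | None = None,
    v_floor_rel: float = 1e-6,
) -> tuple[IMPattern, pd.DataFrame]:
    """Select the measurement frame from candidate sensitivity rows.

    Greedy Gram-volume maximization picks ``counts['volume']`` rows, then the
    top ``counts['l1']`` by L1 norm and top ``counts['l2']`` by L2 norm among
    the remaining candidates (already-selected rows are skipped, so the frame
    holds exactly the requested number of distinct measurements).  Ties break
    on the lowest candidate index.

    If ``v_ref`` (homogeneous reference voltages per candidate) is given,
    candidates whose reference magnitude falls below ``v_floor_rel`` times
    the median are excluded first: their relative voltage differences are
    numerically degenerate.  Returns the pattern and a per-measurement
    selection report.
    """
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    J_all = np.asarray(J_all, dtype=float)
    n_cand = J_all.shape[0]
    if n_cand != len(candidates):
        raise ValueError("J_all rows must match the candidate set")
    eligible = np.arange(n_cand)
    if v_ref is not None:
        v_ref = np.asarray(v_ref)
        floor = v_floor_rel * np.median(np.abs(v_ref))
        eligible = np.flatnonzero(np.abs(v_ref) >= floor)
    total = sum(counts.values())
    if total > len(eligible):
        raise ValueError(
            f"requested {total} measurements but only {len(eligible)} "
            f"eligible candidates"
        )

    order: list[int] = []
    method: list[str] = []
    if counts.get("volume", 0):
        vol_idx, _ = greedy_gram_select(J_all, counts["volume"],
                                        candidates=eligible)
        order.extend(vol_idx)
        method.extend(["volume"] * len(vol_idx))
    taken = set(order)
    l1 = score_l1(J_all)
    l2 = score_l2(J_all)
    for name, scores in (("l1", l1), ("l2", l2)):
        want = counts.get(name, 0)
        if not want:
            continue
        ranked = sorted(
            (i for i in eligible if i not in taken),
            key=lambda i: (-scores[i], i),
        )[:want]
        if len(ranked) < want:
            raise ValueError(f"not enough candidates for the {name} group")
        order.extend(ranked)
        method.extend([name] * want)
        taken.update(ranked)

    report = pd.DataFrame(
        {
            "candidate": order,
            "method": method,
            "inject_a": [candidates.measurements[i].inject[0] for i in order],
            "inject_b": [candidates.measurements[i].inject[1] for i in order],
            "meas_c": [candidates.measurements[i].measure[0] for i in order],
            "meas_d": [candidates.measurements[i].measure[1] for i in order],
            "l1": l1[order],
            "l2": l2[order],
        }
    )
    return candidates.pattern(order), report
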