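"""Matching detected change-point candidates against ground truth.

Detected peaks and true change times are paired greedily by ascending
absolute time difference, one-to-one; a true change point counts as
matched when its paired candidate lies within ``tol`` time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MatchReport", "match_candidates"]


@dataclass(frozen=True)
class MatchReport:
    n_true: int
    n_detected: int
    n_matched: int
    matches: tuple[tuple[int, int], ...]  # (truth, detected) pairs within tol
    unmatched_truth: tuple[int, ...]
    unmatched_detected: tuple[int, ...]
    tol: int

    def to_dict(self) -> dict:
        return {
            "n_true": self.n_true,
            "n_detected": self.n_detected,
            "n_matched": self.n_matched,
            "matches": [list(m) for m in self.matches],
            "unmatched_truth": list(self.unmatched_truth),
            "unmatched_detected": list(self.unmatched_detected),
            "tol": self.tol,
        }


def match_candidates(detected_peaks, truth, tol: int) -> MatchReport:
    """Greedy one-to-one matching by ascending |detected - truth|.

    Ties break deterministically toward the earlier truth time, then the
    earlier detected time; input orderings do not affect the result.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    detected = sorted(int(x) for x in np.asarray(detected_peaks, dtype=int).ravel())
    true_pts = sorted(int(x) for x in np.asarray(truth, dtype=int).ravel())

    pairs = sorted(
        ((abs(dv - tv), tv, dv) for tv in true_pts for dv in detected),
        key=lambda p: (p[0], p[1], p[2]),
    )
    used_truth: set[int] = set()
    used_detected: set[int] = set()
    matches: list[tuple[int, int]] = []
    for delta, tv, dv in pairs:
        if delta > tol:
            break
        if tv in used_truth or dv in used_detected:
            continue
        used_truth.add(tv)
        used_detected.add(dv)
        matches.append((tv, dv))
    matches.sort()
    return MatchReport(
        n_true=len(true_pts),
        n_detected=len(detected),
        n_matched=len(matches),
        matches=tuple(matches),
        unmatched_truth=tuple(tv for tv in true_pts if tv not in used_truth),
        unmatched_detected=tuple(dv for dv in detected if dv not in used_detected),
        tol=int(tol),
    )
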