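"""Scoring detected deletions against truth or against known structure.

Two evaluation regimes. Against simulated truth: each detected deletion is
binned as an exact match (both sites equal the encoded sites), a close
match (both sites within 3 nt) or incorrect. Against structure: a deletion
is a true contact when its two sites are close in space (< 15 A) yet far
in the secondary structure (contact distance > 10, i.e. not simply
base-paired neighbors), and ranked deletion rates are scored by ROC/AUC.

Contact distance is the shortest-path length between two nucleotides in
the graph whose edges connect backbone neighbors (k, k+1) and base pairs
(k, pair_of[k]); a nested helix is traversed in about one step via its pair
edges, which operationalizes "distance after omitting nested helices".
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .deletion_detect import Deletion
from .io_formats import SecondaryStructure, TertiaryCoordinates
from .quantify import DeletionProfile, ShiftConfig, select_top_fraction, shift_sites
from .simulate import TruthRecord

PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


@dataclass
class ContactClassifier:
    """Defines a 'tertiary contact': spatially close (< ``max_angstroms``)
    but distant in secondary structure (contact distance >
    ``min_contact_distance``)."""

    max_angstroms: float = 15.0
    min_contact_distance: int = 10
    distance_anchor: str = "O2'"  # or "base_center"

    def __post_init__(self) -> None:
        if self.max_angstroms <= 0 or self.min_contact_distance <= 0:
            raise ValueError("classifier thresholds must be positive")


@dataclass
class AccuracyReport:
    n_reads_with_truth: int
    n_detected: int
    exact: int
    close: int
    incorrect: int
    undetected: int
    ppv: dict[tuple[int, int], float] = field(default_factory=dict)

    def pct(self, count: int) -> float:
        return 100.0 * count / self.n_reads_with_truth if self.n_reads_with_truth else 0.0

    @property
    def pct_exact(self) -> float:
        return self.pct(self.exact)

    @property
    def pct_close(self) -> float:
        return self.pct(self.close)

    @property
    def pct_incorrect(self) -> float:
        return self.pct(self.incorrect)

    @property
    def pct_detected(self) -> float:
        return self.pct(self.n_reads_with_truth - self.undetected)


def classify_deletion_accuracy(
    detected: Deletion, truth: TruthRecord, tol: int = 3
) -> str:
    """Bin one detection against its read's encoded deletion.

    'exact' when both sites match; 'close' when both are within ``tol``
    nucleotides; 'incorrect' otherwise.
    """
    d5 = abs(detected.five_prime_site - truth.encoded_five)
    d3 = abs(detected.three_prime_site - truth.encoded_three)
    if d5 == 0 and d3 == 0:
        return "exact"
    if d5 <= tol and d3 <= tol:
        return "close"
    return "incorrect"


_RANK = {"exact": 0, "close": 1, "incorrect": 2}


def score_dataset(
    detections: Iterable[Deletion],
    truth: Mapping[str, TruthRecord],
    tol: int = 3,
) -> AccuracyReport:
    """Score per-read detections against a truth set.

    Each read with truth contributes its best detection (exact beats close
    beats incorrect); reads without any detection are tallied as
    undetected. The per-site ppv map gives, for every detected (five,
    three), the fraction of detections there that were exact — the
    interaction-map coloring.
    """
    best: dict[str, str] = {}
    site_total: Counter = Counter()
    site_correct: Counter = Counter()
    n_detected = 0
    for d in detections:
        rec = truth.get(d.read_id)
        if rec is None:
            raise ValueError(f"detection for unknown read_id {d.read_id!r}")
        n_detected += 1
        cat = classify_deletion_accuracy(d, rec, tol)
        prev = best.get(d.read_id)
        if prev is None or _RANK[cat] < _RANK[prev]:
            best[d.read_id] = cat
        key = (d.five_prime_site, d.three_prime_site)
        site_total[key] += 1
        if cat == "exact":
            site_correct[key] += 1
    counts = Counter(best.values())
    ppv = {k: site_correct[k] / t for k, t in site_total.items()}
    return AccuracyReport(
        n_reads_with_truth=len(truth),
        n_detected=n_detected,
        exact=counts["exact"],
        close=counts["close"],
        incorrect=counts["incorrect"],
        undetected=len(truth) - len(best),
        ppv=ppv,
    )


def _adjacency(ss: SecondaryStructure) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(ss.length + 1)]
    for k in range(1, ss.length):
        adj[k].append(k + 1)
        adj[k + 1].append(k)
    for i, j in ss.pair_of.items():
        if j not in adj[i]:
            adj[i].append(j)
    return adj


def contact_distances_from(i: int, ss: SecondaryStructure) -> list[int]:
    """BFS distances from position ``i`` to every position (index 0 unused)."""
    adj = _adjacency(ss)
    dist = [-1] * (ss.length + 1)
    dist[i] = 0
    queue = deque([i])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def contact_distance(i: int, j: int, ss: SecondaryStructure) -> int:
    """Shortest path between nucleotides through backbone and pair edges."""
    if not (1 <= i <= ss.length and 1 <= j <= ss.length):
        raise ValueError(f"positions ({i}, {j}) outside [1, {ss.length}]")
    if i == j:
        return 0
    return contact_distances_from(i, ss)[j]


def _base_center(atoms: Mapping[str, tuple[float, float, float]]):
    ring = PURINE_RING if "N9" in atoms else PYRIMIDINE_RING
    if not all(a in atoms for a in ring):
        return None
    pts = np.array([atoms[a] for a in ring])
    return pts.mean(axis=0)


def spatial_distance(
    i: int, j: int, coords: TertiaryCoordinates, anchor: str = "O2'"
) -> float | None:
    """Euclidean distance (A) between two residues, or None when the anchor
    atoms are unresolved.

    ``anchor`` is ``"O2'"`` (ribose 2'-hydroxyl oxygen) or ``"base_center"``
    (centroid of the base-ring heavy atoms).
    """
    ri, rj = coords.atoms.get(i), coords.atoms.get(j)
    if ri is None or rj is None:
        return None
    if anchor == "base_center":
        pi, pj = _base_center(ri), _base_center(rj)
    else:
        pi = np.asarray(ri["O2'"]) if "O2'" in ri else None
        pj = np.asarray(rj["O2'"]) if "O2'" in rj else None
    if pi is None or pj is None:
        return None
    return float(np.linalg.norm(np.asarray(pi) - np.asarray(pj)))


def distance_distribution(
    profile: DeletionProfile,
    coords: TertiaryCoordinates,
    anchor: str = "O2'",
    fraction: float = 0.03,
) -> tuple[list[float], list[float]]:
    """Observed vs chance through-space distance lists for histogramming.

    Observed: distances of the top-``fraction`` deletions by rate.
    Background: distances over all resolved position pairs.
    """
    top = select_top_fraction(profile, fraction)
    observed = []
    for five, three in sorted(top.entries):
        dist = spatial_distance(five, three, coords, anchor)
        if dist is not None:
            observed.append(dist)
    residues = [r for r in coords.residues()
                if spatial_distance(r, r, coords, anchor) is not None]
    background = []
    for i, j in combinations(residues, 2):
        dist = spatial_distance(i, j, coords, anchor)
        if dist is not None:
            background.append(dist)
    return observed, background


def label_contacts(
    profile: DeletionProfile,
    ss: SecondaryStructure,
    coords: TertiaryCoordinates,
    classifier: ContactClassifier = ContactClassifier(),
) -> tuple[list[float], list[int], int]:
    """Rate/label pairs for ROC analysis, plus the excluded-entry tally.

    Positive label: spatial distance < ``max_angstroms`` and contact
    distance > ``min_contact_distance``. Entries with unresolved spatial
    distance are excluded.
    """
    scores: list[float] = []
    labels: list[int] = []
    excluded = 0
    bfs_cache: dict[int, list[int]] = {}
    for (five, three) in sorted(profile.entries):
        dist = spatial_distance(five, three, coords, classifier.distance_anchor)
        if dist is None:
            excluded += 1
            continue
        if five not in bfs_cache:
            bfs_cache[five] = contact_distances_from(five, ss)
        cd = bfs_cache[five][three]
        positive = dist < classifier.max_angstroms and cd > classifier.min_contact_distance
        scores.append(profile.rate_of((five, three)))
        labels.append(int(positive))
    return scores, labels, excluded


def roc_auc(
    profile: DeletionProfile,
    ss: SecondaryStructure,
    coords: TertiaryCoordinates,
    classifier: ContactClassifier = ContactClassifier(),
) -> tuple[list[tuple[float, float]], float | None]:
    """ROC points and AUC for ranking true contacts by deletion rate.

    Entries sharing a rate enter together (one threshold per distinct
    rate); with a single class present the AUC is undefined and returned
    as None.
    """
    scores, labels, _ = label_contacts(profile, ss, coords, classifier)
    if not labels or len(set(labels)) < 2:
        return [], None
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def shift_grid_auc(
    profile: DeletionProfile,
    ss: SecondaryStructure,
    coords: TertiaryCoordinates,
    classifier: ContactClassifier = ContactClassifier(),
    max_shift: int = 5,
) -> tuple[np.ndarray, tuple[int, int] | None]:
    """AUC over the (shift_5p, shift_3p) grid in [0, max_shift]^2.

    Applied to an *unshifted* profile; returns the grid (NaN where AUC is
    undefined) and the argmax cell, ties resolved toward smaller shifts.
    """
    grid = np.full((max_shift + 1, max_shift + 1), np.nan)
    for a in range(max_shift + 1):
        for b in range(max_shift + 1):
            shifted = shift_sites(profile, ShiftConfig(shift_5p=a, shift_3p=b))
            _, score = roc_auc(shifted, ss, coords, classifier)
            if score is not None:
                grid[a, b] = score
    if np.all(np.isnan(grid)):
        return grid, None
    best = None
    for a in range(max_shift + 1):
        for b in range(max_shift + 1):
            if not math.isnan(grid[a, b]) and (
                best is None or grid[a, b] > grid[best]
            ):
                best = (a, b)
    return grid, best


def summary_stats(profile: DeletionProfile) -> dict[str, Counter]:
    """Deletion-length, rate and per-site-count histograms for reporting."""
    length_hist: Counter = Counter()
    rate_hist: Counter = Counter()
    for (five, three), e in profile.entries.items():
        length_hist[three - five - 1] += e.count
        rate_hist[round(profile.rate_of((five, three)), 4)] += 1
    return {"deletion_length": length_hist, "rate": rate_hist}


def write_summary_tsv(profile: DeletionProfile, path) -> None:
    stats = summary_stats(profile)
    with open(path, "w") as out:
        for name, hist in stats.items():
            for key in sorted(hist):
                out.write(f"{name}\t{key}\t{hist[key]}\n")
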