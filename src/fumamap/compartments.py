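"""Compartment segmentation and per-compartment concentration statistics.

Scans are segmented by k-means with random initial assignment and
Manhattan (L1) distances on mean-centered spectra.  Cluster loadings
(class centroids on the original counts scale) are assigned biological
identities from marker bands: resonance cytochrome-C bands (748, 1127,
1585 cm^-1) mark mitochondria, 785 cm^-1 marks the nucleus, lipid bands
(1301, 1445 cm^-1) mark the membrane, and the lowest-total classes are
the substrate.  Per-compartment concentrations (the apparent values) can
then be background-corrected by subtracting the FH-proficient control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .core import SpectralMap, Spectrum
from .preprocess import band_auc, iterative_polynomial_baseline
from .quantify import ConcentrationMap

__all__ = [
    "ClusterResult",
    "CompartmentAssignment",
    "CompartmentTable",
    "kmeans_manhattan",
    "assign_compartments",
    "compartment_concentrations",
    "background_correct",
    "anova_compartments",
    "classify_tissue_status",
]

COMPARTMENT_ORDER = ("substrate", "nucleus", "membrane", "cytoplasm",
                     "mitochondria")


@dataclass
class ClusterResult:
    """k-means output: per-pixel labels plus per-class loading spectra
    (centroids on the original, non-centered counts scale)."""

    labels: np.ndarray            # (H, W) or (n,) int in 0..k-1
    loadings: np.ndarray          # (k, channels)
    wavenumbers: np.ndarray
    k: int
    seed: int
    metric: str = "manhattan"
    n_iter: int = 0
    meta: dict = field(default_factory=dict)

    def loading_spectrum(self, class_id: int, dwell: float = 1.0) -> Spectrum:
        return Spectrum(self.wavenumbers, self.loadings[class_id],
                        dwell=dwell, meta={"class": class_id})


def _lloyd_l1(X: np.ndarray, labels: np.ndarray, k: int, max_iter: int,
              rng: np.random.Generator, median_update: bool
              ) -> tuple[np.ndarray, np.ndarray, int]:
    """Lloyd iterations with L1 assignment.  Centroid update is the
    arithmetic mean by default (vendor-style k-means with Manhattan
    distances); ``median_update`` selects the L1-consistent k-medians
    variant.  Empty classes are re-seeded from the farthest point."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(k):
            members = X[labels == j]
            if len(members) == 0:
                dist_all = cdist(X, centroids[:j] if j else X[:1],
                                 metric="cityblock").min(axis=1)
                centroids[j] = X[np.argmax(dist_all)]
            elif median_update:
                centroids[j] = np.median(members, axis=0)
            else:
                centroids[j] = members.mean(axis=0)
        dists = cdist(X, centroids, metric="cityblock")
        new_labels = np.argmin(dists, axis=1)
        # re-seed any class that lost all members
        for j in range(k):
            if not np.any(new_labels == j):
                far = np.argmax(dists[np.arange(n), new_labels])
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels, centroids, it


def _plusplus_init(X: np.ndarray, k: int, rng: np.random.Generator
                   ) -> np.ndarray:
    """k-means++ seeding under the L1 metric; returns initial labels."""
    n = X.shape[0]
    chosen = [int(rng.integers(n))]
    d = cdist(X, X[chosen[-1]][None], metric="cityblock")[:, 0]
    for _ in range(k - 1):
        w = d * d
        total = w.sum()
        if total <= 0:
            chosen.append(int(rng.integers(n)))
        else:
            chosen.append(int(rng.choice(n, p=w / total)))
        d = np.minimum(d, cdist(X, X[chosen[-1]][None],
                                metric="cityblock")[:, 0])
    return np.argmin(cdist(X, X[chosen], metric="cityblock"), axis=1)


def kmeans_manhattan(smap: SpectralMap, k: int, seed: int = 0,
                     max_iter: int = 300, median_update: bool = False,
                     n_init: int = 4, init: str = "kmeans++",
                     init_labels: np.ndarray | None = None,
                     original: SpectralMap | None = None) -> ClusterResult:
    """k-means with Manhattan distances.

    ``smap`` should be mean-centered (see
    :func:`fumamap.preprocess.mean_center_scan`); ``original``
    optionally supplies the non-centered map from which the loadings are
    computed (defaults to ``smap``).  ``n_init`` restarts are run and
    the partition with the lowest total L1 inertia is kept.  ``init``
    selects the seeding: 'kmeans++' (default; far better local optima)
    or 'assignment' (uniformly random initial assignment of spectra to
    classes).  ``init_labels`` forces a single run from a given initial
    assignment.  Deterministic given ``seed``.
    """
    X = smap.flat()
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of pixels ({n})")
    if init not in ("kmeans++", "assignment"):
        raise ValueError("init must be 'kmeans++' or 'assignment'")
    rng = np.random.default_rng(seed)

    def _one_run(start: np.ndarray):
        lab, cents, it = _lloyd_l1(X, start.copy(), k, max_iter, rng,
                                   median_update)
        inertia = float(cdist(X, cents, metric="cityblock")[
            np.arange(n), lab].sum())
        return lab, it, inertia

    if init_labels is not None:
        start = np.asarray(init_labels, dtype=int).reshape(n)
        labels, n_iter, _ = _one_run(start)
    else:
        best = None
        for _ in range(max(1, n_init)):
            if init == "kmeans++":
                start = _plusplus_init(X, k, rng)
            else:
                start = rng.integers(0, k, size=n)
            for j in range(k):
                if not np.any(start == j):
                    start[rng.integers(0, n)] = j
            run = _one_run(start)
            if best is None or run[2] < best[2]:
                best = run
        labels, n_iter, _ = best
    source = original if original is not None else smap
    Xorig = source.flat()
    loadings = np.stack([
        Xorig[labels == j].mean(axis=0) if np.any(labels == j)
        else np.zeros(X.shape[1])
        for j in range(k)
    ])
    h, w = smap.shape
    return ClusterResult(labels=labels.reshape(h, w), loadings=loadings,
                         wavenumbers=smap.wavenumbers, k=k, seed=seed,
                         metric="median-l1" if median_update else "manhattan",
                         n_iter=n_iter)


@dataclass
class CompartmentAssignment:
    """class id -> compartment name, with the marker scores that led to
    the assignment."""

    mapping: dict[int, str]
    scores: pd.DataFrame

    def compartment_labels(self, labels: np.ndarray) -> np.ndarray:
        out = np.empty(labels.shape, dtype=object)
        for cid, name in self.mapping.items():
            out[labels == cid] = name
        return out


def _marker_score(loading: Spectrum, center: float,
                  half_width: float = 8.0) -> float:
    """Flat-baseline band area around a marker, clipped at zero."""
    lo = center - 3 * half_width
    return max(0.0, band_auc(loading, (lo, center - half_width),
                             (center - half_width, center + half_width)))


def assign_compartments(result: ClusterResult,
                        substrate_fraction: float = 0.5,
                        mito_fraction: float = 0.5) -> CompartmentAssignment:
    """Assign biological identities to k-means classes via marker bands.

    Classes whose total fingerprint AUC is below ``substrate_fraction``
    of the brightest class are substrate (there may be several).  Of the
    rest, classes whose cytochrome-C score reaches ``mito_fraction`` of
    the top score are mitochondria (FH-deficient scans can yield two),
    the highest 785 cm^-1 score is the nucleus, the highest lipid score
    is the membrane, and the remainder is cytoplasm.
    """
    k = result.k
    wn = result.wavenumbers
    rows = []
    for j in range(k):
        raw = Spectrum(wn, result.loadings[j], dwell=1.0)
        # score on the baseline-corrected loading so fluorescence level
        # does not masquerade as band content
        loading = iterative_polynomial_baseline(raw)[1]
        total = float(np.trapezoid(
            np.clip(loading.counts, 0.0, None), wn))
        cytc = sum(_marker_score(loading, c) for c in (748.0, 1127.0, 1585.0))
        nucleus = _marker_score(loading, 785.0)
        lipid = sum(_marker_score(loading, c) for c in (1301.0, 1445.0))
        rows.append({"class": j, "total_auc": total, "cytc": cytc,
                     "nucleus": nucleus, "lipid": lipid})
    scores = pd.DataFrame(rows).set_index("class")

    mapping: dict[int, str] = {}
    max_total = scores["total_auc"].max()
    marker_sum = scores[["cytc", "nucleus", "lipid"]].sum(axis=1)
    # substrate: dim classes, or classes with essentially no biological
    # marker content (covers scans that contain no cell at all)
    substrate = scores.index[
        (scores["total_auc"] < substrate_fraction * max_total)
        | (marker_sum < 0.02 * scores["total_auc"])].tolist()
    if not substrate:
        substrate = [int(scores["total_auc"].idxmin())]
    for j in substrate:
        mapping[j] = "substrate"
    remaining = [j for j in scores.index if j not in mapping]

    if remaining:
        top_cytc = scores.loc[remaining, "cytc"].max()
        mito = [j for j in remaining
                if top_cytc > 0 and scores.loc[j, "cytc"]
                >= mito_fraction * top_cytc]
        if not mito and remaining:
            mito = [int(scores.loc[remaining, "cytc"].idxmax())]
        for j in mito:
            mapping[j] = "mitochondria"
        remaining = [j for j in remaining if j not in mapping]
    if remaining:
        j = int(scores.loc[remaining, "nucleus"].idxmax())
        mapping[j] = "nucleus"
        remaining.remove(j)
    if remaining:
        j = int(scores.loc[remaining, "lipid"].idxmax())
        mapping[j] = "membrane"
        remaining.remove(j)
    for j in remaining:
        mapping[j] = "cytoplasm"

    present = set(mapping.values())
    missing = set(COMPARTMENT_ORDER) - present
    if missing:
        warnings.warn(
            f"fewer classes than compartments; unassigned: {sorted(missing)}")
    return CompartmentAssignment(mapping=mapping, scores=scores)


@dataclass
class CompartmentTable:
    """Per-compartment concentration statistics (the Table-1 analogue)."""

    table: pd.DataFrame           # index: compartment; mean_mM, sd_mM, n
    cell_line: str = ""
    corrected: bool = False

    def mean(self, compartment: str) -> float:
        return float(self.table.loc[compartment, "mean_mM"])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "cell_line", self.cell_line)
        out["corrected"] = self.corrected
        out.to_csv(path)


def compartment_concentrations(cmap: ConcentrationMap,
                               assignment: CompartmentAssignment,
                               labels: np.ndarray,
                               cell_line: str = "") -> CompartmentTable:
    """Mean +/- SD concentration per compartment.

    The SD is the variability of all pixel concentrations pooled within
    each (possibly merged) cluster class.
    """
    if labels.shape != cmap.shape:
        raise ValueError("label map shape must match concentration map")
    comp_labels = assignment.compartment_labels(labels)
    rows = []
    present = [c for c in COMPARTMENT_ORDER
               if c in set(assignment.mapping.values())]
    for name in present:
        sel = (comp_labels == name) & cmap.mask
        vals = cmap.values[sel]
        if vals.size == 0:
            rows.append({"compartment": name, "mean_mM": np.nan,
                         "sd_mM": np.nan, "n": 0})
        else:
            rows.append({"compartment": name,
                         "mean_mM": float(vals.mean()),
                         "sd_mM": float(vals.std(ddof=1))
                         if vals.size > 1 else 0.0,
                         "n": int(vals.size)})
    table = pd.DataFrame(rows).set_index("compartment")
    return CompartmentTable(table=table, cell_line=cell_line)


def background_correct(ko: CompartmentTable,
                       wt: CompartmentTable) -> CompartmentTable:
    """Subtract the FH-proficient (WT) apparent means from the KO means.

    The WT signal in the fumarate window is background (cytochrome-C and
    similar), so the difference estimates true fumarate.  SDs are
    carried unchanged from the KO table; no variance propagation.
    """
    if set(ko.table.index) != set(wt.table.index):
        raise ValueError(
            f"compartment sets differ: {sorted(ko.table.index)} vs "
            f"{sorted(wt.table.index)}"
        )
    out = ko.table.copy()
    out["mean_mM"] = ko.table["mean_mM"] - wt.table.loc[ko.table.index,
                                                        "mean_mM"]
    return CompartmentTable(table=out, cell_line=ko.cell_line,
                            corrected=True)


def anova_compartments(cmap: ConcentrationMap, labels: np.ndarray,
                       assignment: CompartmentAssignment,
                       groups: tuple[str, ...]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across compartments, from the
    standard between/within sums of squares.  Returns (F, p)."""
    comp_labels = assignment.compartment_labels(labels)
    samples = []
    for name in groups:
        vals = cmap.values[(comp_labels == name) & cmap.mask]
        if vals.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 pixels")
        samples.append(vals)
    return anova_oneway(samples)


def anova_oneway(samples: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA from sums of squares (textbook formulas)."""
    if len(samples) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(samples)
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n_total - k
    if df_w <= 0 or ss_within <= 0:
        raise ValueError("degenerate groups: no within-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def classify_tissue_status(cmap: ConcentrationMap, lod: float,
                           tissue_mask: np.ndarray) -> tuple[str, float]:
    """Call the Fh1 genotype of a tissue scan from the fraction of
    tissue pixels above the LOD.  Returns (call, fraction); the call is
    'Fh1-/-' iff the majority of tissue pixels exceed the LOD."""
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    sel = tissue_mask & cmap.mask
    if not sel.any():
        raise ValueError("tissue mask selects no valid pixels")
    fraction = float((cmap.values[sel] > lod).mean())
    call = "Fh1-/-" if fraction > 0.5 else "Fh1fl/fl"
    return call, fraction
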