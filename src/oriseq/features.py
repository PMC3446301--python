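"""Origin sequence classification: RC-collapsed k-mer features, motif scores, SVMs.

Positive loci are the intergenic portions of 1-kb windows on either side of
each replication peak (windows of peaks closer than 2 kb merged once);
background loci are equally many random windows with the same intergenic
masking, drawn outside 8-kb halos around even sub-threshold peaks so that
weak origins do not contaminate the negatives.

Features are the frequencies of every k-mer for k = 1..6 with a k-mer and its
reverse complement collapsed to one class (6A is the same feature as 6T):
2 + 10 + 32 + 136 + 512 + 2080 = 2,772 classes in total (``4^k/2`` for odd k,
``(4^k + 4^{k/2})/2`` for even k, counting the self-complementary k-mers
once).  Each locus vector is scaled to unit Euclidean norm.  Position weight
matrix motifs enter as one cumulative-score column each — the sum over both
strands and all positions of the positive part of the log-odds score —
affine-rescaled to the pooled mean and SD of the k-mer columns so the two
feature kinds are commensurate in a linear-kernel SVM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "PWM",
    "LocusSet",
    "FeatureMatrix",
    "EvaluationResult",
    "SVMModel",
    "N_KMER_FEATURES",
    "KMER_CLASS_COUNTS",
    "kmer_class_names",
    "kmer_features",
    "extract_loci",
    "build_feature_matrix",
    "auroc",
    "feature_auroc",
    "motif_score",
    "train_svm_cv",
    "train_svm",
    "cross_apply",
]

log = logging.getLogger(__name__)

KMAX = 6
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE_CHARS = "ACGT"


# ---------------------------------------------------------------------------
# reverse-complement-collapsed k-mer alphabet


def _rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Numeric code of the reverse complement of each k-mer code."""
    rc = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (c % 4))
        c //= 4
    return rc


@lru_cache(maxsize=1)
def _kmer_tables():
    """Lookup tables mapping k-mer codes to global RC-class indices.

    Returns (lookups, names, offsets): ``lookups[k-1]`` maps each of the 4^k
    codes to a global column index; ``names`` lists canonical k-mers in
    column order (sorted by k, then lexicographically); ``offsets[k-1]`` is
    the first column of each k block.
    """
    lookups, names, offsets = [], [], []
    offset = 0
    for k in range(1, KMAX + 1):
        codes = np.arange(4**k)
        canon = np.minimum(codes, _rc_codes(codes, k))
        uniq = np.unique(canon)   # numeric order == lexicographic for ACGT
        lookups.append(np.searchsorted(uniq, canon) + offset)
        for code in uniq:
            digits = []
            c = int(code)
            for _ in range(k):
                digits.append(_BASE_CHARS[c % 4])
                c //= 4
            names.append("".join(reversed(digits)))
        offsets.append(offset)
        offset += len(uniq)
    return lookups, names, offsets


KMER_CLASS_COUNTS = {
    k: int(np.unique(np.minimum(np.arange(4**k), _rc_codes(np.arange(4**k), k))).size)
    for k in range(1, KMAX + 1)
}
N_KMER_FEATURES = sum(KMER_CLASS_COUNTS.values())  # 2,772


def kmer_class_names() -> list[str]:
    """Canonical (lexicographically smaller of k-mer/revcomp) names, column order."""
    return list(_kmer_tables()[1])


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    codes = np.full(len(arr), 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def kmer_features(sequence: str) -> np.ndarray:
    """RC-collapsed k-mer frequency vector (k = 1..6), unit Euclidean norm.

    Frequencies are window counts divided by ``L - k + 1``; windows containing
    N are skipped but still count in the denominator.  Sequences shorter than
    6 bp cannot host every k and raise.
    """
    if len(sequence) < KMAX:
        raise ValueError(f"sequence length {len(sequence)} < {KMAX}")
    lookups, _, _ = _kmer_tables()
    b = _encode(sequence)
    valid_base = b < 4
    vec = np.zeros(N_KMER_FEATURES)
    for k in range(1, KMAX + 1):
        nwin = len(b) - k + 1
        codes = np.zeros(nwin, dtype=np.int64)
        ok = np.ones(nwin, dtype=bool)
        for j in range(k):
            codes = codes * 4 + np.where(valid_base[j : j + nwin], b[j : j + nwin], 0)
            ok &= valid_base[j : j + nwin]
        counts = np.bincount(lookups[k - 1][codes[ok]], minlength=N_KMER_FEATURES)
        vec += counts / nwin
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


# ---------------------------------------------------------------------------
# position weight matrices


@dataclass
class PWM:
    """Probability matrix over positions x ACGT, with background and pseudocount."""

    motif_id: str
    matrix: np.ndarray                       # shape (w, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (width, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-4):
            raise ValueError("PWM rows must sum to 1")

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, weight: float = 0.85) -> "PWM":
        w = len(consensus)
        mat = np.full((w, 4), (1 - weight) / 3)
        for i, base in enumerate(consensus.upper()):
            mat[i, _BASE_INDEX[base]] = weight
        return cls(motif_id=motif_id, matrix=mat)

    @classmethod
    def from_biomotif(cls, motif) -> "PWM":
        """Adapt a Bio.motifs motif (e.g. parsed from MEME minimal format)."""
        counts = np.array([[motif.counts[b][i] for b in "ACGT"] for i in range(motif.length)], dtype=float)
        mat = counts / counts.sum(axis=1, keepdims=True)
        bg = np.array([motif.background.get(b, 0.25) for b in "ACGT"]) if motif.background else np.full(4, 0.25)
        return cls(motif_id=motif.name or "motif", matrix=mat, background=bg)

    def log_odds(self) -> np.ndarray:
        p = self.matrix + self.pseudocount
        p /= p.sum(axis=1, keepdims=True)
        bg = self.background / self.background.sum()
        return np.log2(p / bg)

    def consensus(self) -> str:
        return "".join(_BASE_CHARS[i] for i in np.argmax(self.matrix, axis=1))

    def sample(self, rng: np.random.Generator) -> str:
        return "".join(
            _BASE_CHARS[rng.choice(4, p=row / row.sum())] for row in self.matrix
        )

    def is_palindromic(self, tol: float = 0.05) -> bool:
        rc = self.matrix[::-1, ::-1]
        return bool(np.max(np.abs(rc - self.matrix)) < tol)


def motif_score(sequence: str, pwm: PWM) -> float:
    """Cumulative motif score: sum over both strands and all positions of the
    positive part of the log-odds window score.

    Sequences shorter than the motif score 0.  (Rescaling to k-mer feature
    statistics is applied matrix-wide in :func:`build_feature_matrix`.)
    """
    w = len(pwm.matrix)
    if len(sequence) < w:
        return 0.0
    lo = pwm.log_odds()
    b = _encode(sequence)
    nwin = len(b) - w + 1
    total = 0.0
    for strand_lo in (lo, lo[::-1, ::-1]):  # reverse strand = reversed complemented matrix
        scores = np.zeros(nwin)
        ok = np.ones(nwin, dtype=bool)
        for j in range(w):
            col = b[j : j + nwin]
            good = col < 4
            ok &= good
            scores += np.where(good, strand_lo[j][np.minimum(col, 3)], 0.0)
        total += float(np.sum(np.maximum(scores[ok], 0.0)))
    return total


# ---------------------------------------------------------------------------
# locus extraction


@dataclass
class LocusSet:
    sequences: list[str]
    labels: np.ndarray                 # 1 = positive (origin), 0 = background
    provenance: list[str] = field(default_factory=list)
    n_dropped: int = 0


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not windows:
        return []
    windows = sorted(windows)
    merged = [list(windows[0])]
    for s, e in windows[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intergenic_sequence(
    chrom_seq: str, start: int, end: int, genes: list[tuple[int, int]]
) -> str:
    """Concatenated intergenic fragments of [start, end)."""
    start, end = max(0, start), min(len(chrom_seq), end)
    pieces, pos = [], start
    for gs, ge in genes:
        if ge <= pos:
            continue
        if gs >= end:
            break
        if gs > pos:
            pieces.append(chrom_seq[pos:gs])
        pos = max(pos, ge)
        if pos >= end:
            break
    if pos < end:
        pieces.append(chrom_seq[pos:end])
    return "".join(pieces)


def extract_loci(
    peak_positions: list[tuple[str, float]],
    genome: dict[str, str],
    gene_intervals: list[tuple[str, int, int]],
    subthreshold_positions: list[tuple[str, float]] | None = None,
    flank: int = 1000,
    merge_dist: int = 2000,
    halo: int = 8000,
    min_len: int = 100,
    seed: int = 0,
) -> LocusSet:
    """Build positive and background loci for sequence model training.

    Positives: intergenic portions of ``peak +/- flank`` windows, with windows
    of peaks closer than ``merge_dist`` merged and counted once.  Backgrounds:
    an equal number of random same-width windows with identical intergenic
    masking, excluding ``halo`` bp around every sub-threshold peak.  Loci whose
    intergenic portion is shorter than ``min_len`` are dropped (a fully genic
    peak window contributes nothing) and counted in ``n_dropped``.
    """
    if not peak_positions:
        raise ValueError("no peaks: cannot extract positive loci")
    genes_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in gene_intervals:
        genes_by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    for chrom in genes_by_chrom:
        genes_by_chrom[chrom].sort()

    halo_centers: dict[str, np.ndarray] = {}
    for chrom, pos in subthreshold_positions or peak_positions:
        halo_centers.setdefault(chrom, [])
    for chrom, pos in subthreshold_positions or peak_positions:
        halo_centers[chrom].append(pos)
    halo_centers = {c: np.sort(np.array(v)) for c, v in halo_centers.items()}

    sequences, labels, provenance = [], [], []
    n_dropped = 0
    for chrom in genome:
        pos_here = sorted(p for c, p in peak_positions if c == chrom)
        windows = [(int(p) - flank, int(p) + flank) for p in pos_here]
        # peaks closer than merge_dist have overlapping windows: merge once
        for s, e in _merge_windows(windows):
            seq = _intergenic_sequence(genome[chrom], s, e, genes_by_chrom.get(chrom, []))
            if len(seq) >= min_len:
                sequences.append(seq)
                labels.append(1)
                provenance.append(f"{chrom}:{s}-{e}")
            else:
                n_dropped += 1
    n_pos = sum(labels)
    if n_pos == 0:
        raise ValueError("all positive loci were dropped (fully genic peak windows)")
    if n_dropped:
        log.warning("extract_loci: dropped %d fully-genic positive loci", n_dropped)

    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    p_chrom = lengths / lengths.sum()
    n_bg, attempts = 0, 0
    while n_bg < n_pos and attempts < 1000 * n_pos:
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=p_chrom))]
        center = int(rng.integers(flank, len(genome[chrom]) - flank))
        near = halo_centers.get(chrom)
        if near is not None and len(near):
            i = np.searchsorted(near, center)
            if any(
                0 <= j < len(near) and abs(near[j] - center) <= halo for j in (i - 1, i)
            ):
                continue
        seq = _intergenic_sequence(
            genome[chrom], center - flank, center + flank, genes_by_chrom.get(chrom, [])
        )
        if len(seq) >= min_len:
            sequences.append(seq)
            labels.append(0)
            provenance.append(f"{chrom}:{center - flank}-{center + flank}:random")
            n_bg += 1
    if n_bg < n_pos:
        raise ValueError("could not draw enough background loci outside peak halos")
    return LocusSet(
        sequences=sequences,
        labels=np.array(labels),
        provenance=provenance,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# feature matrices


@dataclass
class FeatureMatrix:
    X: np.ndarray
    labels: np.ndarray
    columns: list[str]
    n_kmer: int = N_KMER_FEATURES
    motif_stats: dict[str, tuple[float, float]] = field(default_factory=dict)


def build_feature_matrix(loci: LocusSet, pwms: list[PWM] | None = None) -> FeatureMatrix:
    """k-mer columns plus one rescaled cumulative-score column per PWM.

    Raw motif scores are affine-mapped to have the pooled mean and SD of the
    k-mer feature entries across these loci, so both feature kinds live on
    one scale for the linear SVM.
    """
    K = np.array([kmer_features(s) for s in loci.sequences])
    columns = kmer_class_names()
    stats: dict[str, tuple[float, float]] = {}
    blocks = [K]
    if pwms:
        pooled_mean = float(K.mean())
        pooled_sd = float(K.std())
        for pwm in pwms:
            raw = np.array([motif_score(s, pwm) for s in loci.sequences])
            sd = raw.std()
            if sd == 0:
                scaled = np.full_like(raw, pooled_mean)
            else:
                scaled = (raw - raw.mean()) / sd * pooled_sd + pooled_mean
            stats[pwm.motif_id] = (float(raw.mean()), float(sd))
            blocks.append(scaled[:, None])
            columns = columns + [pwm.motif_id]
    X = np.hstack(blocks)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite entries")
    return FeatureMatrix(X=X, labels=loci.labels.copy(), columns=columns, motif_stats=stats)


# ---------------------------------------------------------------------------
# evaluation


def auroc(scores, labels) -> float:
    """Area under the ROC curve, equal to P(score+ > score-) + P(tie)/2.

    Computed from the rank-sum form with midranks, which matches trapezoidal
    integration of the empirical ROC under ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def feature_auroc(matrix: FeatureMatrix) -> dict[str, float]:
    """auROC of each feature column used directly as a score.

    Values below 0.5 are reported as-is: they mark negative predictors (a
    feature depleted at origins), and ``auroc(x) + auroc(-x) = 1``.
    """
    return {
        name: auroc(matrix.X[:, j], matrix.labels)
        for j, name in enumerate(matrix.columns)
    }


@dataclass
class EvaluationResult:
    auroc: float
    per_fold: list[float]
    fold_assignment: np.ndarray
    seed: int


@dataclass
class SVMModel:
    clf: SVC
    columns: list[str]


def train_svm_cv(
    matrix: FeatureMatrix, folds: int = 5, seed: int = 0, C: float = 1.0
) -> EvaluationResult:
    """Stratified k-fold cross-validated linear-kernel SVM.

    Each fold trains on the remaining folds and scores its held-out loci with
    the decision function; the reported auROC pools all held-out scores.
    """
    y = matrix.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"class counts {counts.tolist()} cannot be stratified into {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    assignment = np.zeros(len(y), dtype=int)
    per_fold = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(matrix.X, y)):
        clf = SVC(kernel="linear", C=C)
        clf.fit(matrix.X[train_idx], y[train_idx])
        scores[test_idx] = clf.decision_function(matrix.X[test_idx])
        assignment[test_idx] = fold
        per_fold.append(auroc(scores[test_idx], y[test_idx]))
    return EvaluationResult(
        auroc=auroc(scores, y), per_fold=per_fold, fold_assignment=assignment, seed=seed
    )


def train_svm(matrix: FeatureMatrix, C: float = 1.0) -> SVMModel:
    """Fit a linear-kernel SVM on the full matrix (for cross-dataset application)."""
    clf = SVC(kernel="linear", C=C)
    clf.fit(matrix.X, matrix.labels)
    return SVMModel(clf=clf, columns=list(matrix.columns))


def cross_apply(model: SVMModel, matrix: FeatureMatrix) -> float:
    """Score a frozen model on another dataset's matrix; return auROC."""
    if model.columns != matrix.columns:
        for a, b in zip(model.columns, matrix.columns):
            if a != b:
                raise ValueError(f"feature column mismatch: model {a!r} vs matrix {b!r}")
        raise ValueError(
            f"feature column count mismatch: {len(model.columns)} vs {len(matrix.columns)}"
        )
    return auroc(model.clf.decision_function(matrix.X), matrix.labels)
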