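"""Alignment-only sequence variability profiles and homolog set filtering.

Profiles computed here need only the MSA column content: Shannon entropy
(EN), the Karlin & Brocchieri sum-of-pairs conservation score (KBSP) and the
Valdar & Thornton sequence-weighted sum-of-pairs score (VTSP). Profiles that
use the phylogeny (CS, ET) live in :mod:`sitevar.phylo`.

Gap convention: gaps are excluded from column frequencies and from pair
sums; a column with fewer than two non-gap residues gets a missing (NaN)
score. Setting ``gap_score_zero=True`` on the sum-of-pairs scorers instead
scores gap-containing pairs as 0 similarity while keeping them in the pair
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io import AMINO_ACIDS, GAP, MSAlignment, SiteProfile
from .substitution import AA_INDEX, SubstitutionScores, jtt250_scores

logger = logging.getLogger(__name__)


def site_frequencies(msa: MSAlignment, column: int) -> np.ndarray | None:
    """20-vector of amino acid frequencies at a column, over non-gap rows.

    Returns None for an all-gap column (frequencies undefined).
    """
    col = msa.column(column)
    counts = np.zeros(20)
    for c in col:
        if c in AA_INDEX:
            counts[AA_INDEX[c]] += 1
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def _column_entropy(chars) -> float:
    counts: dict[str, int] = {}
    for c in chars:
        if c != GAP and c in AA_INDEX:
            counts[c] = counts.get(c, 0) + 1
    n = sum(counts.values())
    if n == 0:
        return np.nan
    f = np.array(list(counts.values()), dtype=float) / n
    return float(-(f * np.log(f)).sum())


def compute_entropy(msa: MSAlignment) -> SiteProfile:
    """Shannon entropy EN_i = -sum_a f_ia ln f_ia per mapped site (nats)."""
    if msa.n_rows < 2:
        raise ValueError("entropy needs at least 2 sequences")
    values = [_column_entropy(msa.column(c)) for c in msa.mapped_columns]
    return SiteProfile(np.array(values), "EN")


def _sum_of_pairs(
    msa: MSAlignment,
    matrix: np.ndarray,
    weights: np.ndarray | None,
    gap_score_zero: bool,
) -> np.ndarray:
    M = msa.n_rows
    values = np.empty(len(msa.mapped_columns))
    w = np.ones(M) if weights is None else np.asarray(weights, float)
    for out, c in enumerate(msa.mapped_columns):
        col = msa.column(c)
        idx = np.array([AA_INDEX.get(ch, -1) for ch in col])
        valid = idx >= 0
        if valid.sum() < 2:
            values[out] = np.nan
            continue
        iv, wv = idx[valid], w[valid]
        sub = matrix[np.ix_(iv, iv)]
        # sum over unordered pairs k < l of w_k w_l m(a_k, a_l)
        total = (wv @ sub @ wv - np.sum(wv**2 * np.diag(sub))) / 2.0
        if gap_score_zero:
            denom = (w.sum() ** 2 - np.sum(w**2)) / 2.0
        else:
            denom = (wv.sum() ** 2 - np.sum(wv**2)) / 2.0
        values[out] = total / denom if denom > 0 else np.nan
    return values


def compute_kbsp(
    msa: MSAlignment,
    scores: SubstitutionScores | None = None,
    gap_score_zero: bool = False,
) -> SiteProfile:
    """Karlin & Brocchieri sum-of-pairs conservation score.

    Mean over all sequence pairs of the unit-diagonal normalized JTT250
    similarity of the pair's residues; 1 exactly at a conserved column.
    """
    if msa.n_rows < 2:
        raise ValueError("sum-of-pairs needs at least 2 sequences")
    scores = scores or jtt250_scores()
    values = _sum_of_pairs(msa, scores.kb_normalized, None, gap_score_zero)
    return SiteProfile(values, "KBSP")


def sequence_weights(msa: MSAlignment) -> np.ndarray:
    """Valdar & Thornton sequence weights: mean distance to the other rows.

    Distance between two rows is 1 minus their fractional identity over
    shared non-gap columns. Redundant (near-duplicate) sequences get small
    weights. Degenerate all-identical alignments fall back to equal weights.
    """
    M = msa.n_rows
    rows = [np.array([AA_INDEX.get(c, -1) for c in r]) for r in msa.rows]
    D = np.zeros((M, M))
    for k in range(M):
        for l in range(k + 1, M):
            both = (rows[k] >= 0) & (rows[l] >= 0)
            n = int(both.sum())
            if n == 0:
                d = 1.0
            else:
                d = 1.0 - (rows[k][both] == rows[l][both]).mean()
            D[k, l] = D[l, k] = d
    w = D.sum(axis=1) / max(M - 1, 1)
    if w.sum() == 0:
        w = np.ones(M)
    return w


def compute_vtsp(
    msa: MSAlignment,
    scores: SubstitutionScores | None = None,
    gap_score_zero: bool = False,
) -> SiteProfile:
    """Valdar & Thornton sum-of-pairs score with sequence weighting.

    Weighted mean over sequence pairs of the min-max normalized JTT250
    similarity; weights damp the influence of closely related sequences.
    """
    if msa.n_rows < 2:
        raise ValueError("sum-of-pairs needs at least 2 sequences")
    scores = scores or jtt250_scores()
    w = sequence_weights(msa)
    values = _sum_of_pairs(msa, scores.vt_normalized, w, gap_score_zero)
    return SiteProfile(values, "VTSP")


# ---------------------------------------------------------------------------
# homolog filtering


@dataclass
class FilterVerdict:
    name: str
    kept: bool
    reason: str  # "kept", "identity>95%", "length<60%", "overlap<10%", "capped"
    identity_to_query: float


def _aligner() -> Align.PairwiseAligner:
    # Needleman-Wunsch with free end gaps (semi-global), BLOSUM62, 11/1 gap
    # costs: fragments align to their true span rather than being stretched
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _identity_and_overlap(aligner, query: str, cand: str) -> tuple[float, float]:
    # identity = matches / shorter sequence length (the CD-HIT convention);
    # overlap = aligned span on the query / query length
    aln = aligner.align(query, cand)[0]
    qa, ca = aln[0], aln[1]
    matches = 0
    qpos_first = qpos_last = None
    qpos = 0
    for qc, cc in zip(qa, ca):
        if qc != "-" and cc != "-":
            if qpos_first is None:
                qpos_first = qpos
            qpos_last = qpos
            if qc == cc:
                matches += 1
        if qc != "-":
            qpos += 1
    identity = matches / min(len(query), len(cand))
    overlap = (
        (qpos_last - qpos_first + 1) / len(query) if qpos_first is not None else 0.0
    )
    return identity, overlap


def filter_homologs(
    query: str,
    candidates: dict[str, str],
    max_keep: int = 300,
    identity_cap: float = 0.95,
    min_length_frac: float = 0.60,
    min_overlap: float = 0.10,
) -> tuple[dict[str, str], list[FilterVerdict]]:
    """Filter a homolog set the way the ConSurf-style protocol prescribes.

    Removes candidates (1) more than 95% identical to the query, (2) shorter
    than 60% of the query, (3) fragments overlapping the query by under 10%;
    then caps the survivors at ``max_keep`` representatives by greedy identity
    clustering (the clustering threshold is lowered from 100% in 1% steps
    until the cluster count fits), keeping representatives closest to the
    query and topping up to the cap with the remaining closest sequences.

    Identity is computed on the pairwise global alignment of each candidate
    to the query; overlap is the aligned span on the query divided by the
    query length.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    aligner = _aligner()
    verdicts: list[FilterVerdict] = []
    survivors: list[tuple[str, str, float]] = []
    for name, seq in candidates.items():
        identity, overlap = _identity_and_overlap(aligner, query, seq)
        if identity > identity_cap:
            verdicts.append(FilterVerdict(name, False, "identity>95%", identity))
        elif len(seq) < min_length_frac * len(query):
            verdicts.append(FilterVerdict(name, False, "length<60%", identity))
        elif overlap < min_overlap:
            verdicts.append(FilterVerdict(name, False, "overlap<10%", identity))
        else:
            survivors.append((name, seq, identity))

    if len(survivors) <= max_keep:
        kept_names = {name for name, _, _ in survivors}
    else:
        kept_names = _cap_by_clustering(aligner, survivors, max_keep)

    kept: dict[str, str] = {}
    for name, seq, identity in survivors:
        if name in kept_names:
            kept[name] = seq
            verdicts.append(FilterVerdict(name, True, "kept", identity))
        else:
            verdicts.append(FilterVerdict(name, False, "capped", identity))
    return kept, verdicts


def _cap_by_clustering(aligner, survivors, max_keep: int) -> set[str]:
    # order by closeness to the query: representatives are query-proximal
    ordered = sorted(survivors, key=lambda t: (-t[2], t[0]))
    cache: dict[tuple[str, str], float] = {}

    def pair_identity(a, b) -> float:
        key = (a[0], b[0])
        if key not in cache:
            cache[key] = _identity_and_overlap(aligner, a[1], b[1])[0]
        return cache[key]

    for threshold in np.arange(1.00, -0.01, -0.01):
        reps: list[tuple[str, str, float]] = []
        for cand in ordered:
            if not any(pair_identity(cand, rep) >= threshold for rep in reps):
                reps.append(cand)
            if len(reps) > max_keep:
                break
        if len(reps) <= max_keep:
            kept = {r[0] for r in reps}
            for cand in ordered:  # top up to the cap with query-proximal rest
                if len(kept) >= max_keep:
                    break
                kept.add(cand[0])
            return kept
    raise RuntimeError("clustering failed to reach the cap")  # pragma: no cover
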