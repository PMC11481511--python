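"""Fragment-based average nucleotide identity (ANI).

The query sequence is cut into consecutive non-overlapping fragments
(1,020 bp by default; a shorter tail is kept if it is at least 100 bp) and
each fragment is locally aligned against the whole subject under an affine
scoring contract (match +1, mismatch -1, gap open -5, gap extend -1). A
fragment is retained iff its best alignment spans at least 70% of the
fragment and reaches at least 30% identity. The pair's identity is the
alignment-length-weighted mean identity over retained fragments; coverage
is the fraction of query bases inside retained alignments. Pairs with no
retained fragment score identity 0 and coverage 0 — unalignable is zero,
not missing, which is what makes pooled intra-genome ANI means meaningful.

The resulting matrix pair (identity, coverage) is asymmetric: rows are
queries, columns subjects, both in percent.

Backends: ``seeded`` (default) locates each fragment in the subject by
exact 16-mer matches and runs a diagonally banded Smith-Waterman around the
seed diagonals; ``exact`` runs the exhaustive full-matrix reference. The
two share scoring and tie-breaking, and agree whenever the optimal path
lies inside the band (see the oracle tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import _align
from .errors import ParameterError

__all__ = [
    "AniParams",
    "AniResult",
    "AniMatrix",
    "fragment_sequence",
    "compute_pairwise_ani",
    "compute_ani_matrix",
]


@dataclass(frozen=True)
class AniParams:
    """Tunable parameters of the fragment-ANI computation."""

    fragment_size: int = 1020
    min_tail: int = 100
    match: int = 1
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -1
    min_fragment_aln_frac: float = 0.70  # aligned span / fragment length
    min_fragment_identity: float = 0.30  # matches / alignment length
    k: int = 16
    band_pad: int = 32
    seed_stride: int = 4  # query k-mers sampled every this many positions
    seed_diag_window: int = 300  # seeds further than this from the median are noise
    backend: str = "seeded"

    def __post_init__(self):
        if self.fragment_size < 1 or self.min_tail < 1:
            raise ParameterError("fragment_size and min_tail must be positive")
        if self.backend not in ("seeded", "exact"):
            raise ParameterError("backend must be 'seeded' or 'exact'")


@dataclass(frozen=True)
class AniResult:
    """One ordered query/subject comparison (percent scales)."""

    query_id: str
    subject_id: str
    identity: float
    coverage: float
    n_fragments_retained: int


def fragment_sequence(seq, fragment_size: int = 1020, min_tail: int = 100):
    """Half-open offsets of consecutive non-overlapping fragments.

    The final short fragment is retained only if it is at least
    ``min_tail`` bp long.
    """
    n = len(seq)
    if n == 0:
        raise ParameterError("cannot fragment an empty sequence")
    if fragment_size < 1:
        raise ParameterError("fragment_size must be positive")
    out = []
    for start in range(0, n, fragment_size):
        end = min(start + fragment_size, n)
        if end - start == fragment_size or end - start >= min_tail:
            out.append((start, end))
    return out


class _SeqData:
    """Per-sequence precomputation shared across pairwise comparisons.

    As a subject, a sequence exposes its complete sorted k-mer index; as a
    query, only every ``seed_stride``-th k-mer is looked up — at the
    identities this package resolves, dozens of sampled seeds per fragment
    survive, which is ample to locate the band.
    """

    __slots__ = ("arr", "frags", "sampled_kmers", "sampled_at",
                 "kmer_sorted", "kmer_pos", "length")

    def __init__(self, seq: str, params: AniParams):
        self.arr = _align.encode(seq)
        self.length = self.arr.shape[0]
        self.frags = fragment_sequence(seq, params.fragment_size, params.min_tail)
        kmers = _align.kmer_codes(self.arr, params.k)
        order = np.argsort(kmers, kind="stable")
        self.kmer_sorted = kmers[order]
        self.kmer_pos = order.astype(np.int64)
        self.sampled_at = np.arange(0, kmers.shape[0], params.seed_stride, dtype=np.int64)
        self.sampled_kmers = kmers[self.sampled_at]


def _align_fragment_seeded(qdat: _SeqData, sdat: _SeqData, f0: int, f1: int,
                           hit: np.ndarray, hit_pos: np.ndarray, params: AniParams):
    """Banded alignment of query fragment [f0, f1) against the subject."""
    k = params.k
    top = f1 - k + 1
    if top <= f0:
        return None
    lo, hi = np.searchsorted(qdat.sampled_at, [f0, top])
    frag_hit = hit[lo:hi]
    if not frag_hit.any():
        return None
    qpos = qdat.sampled_at[lo:hi][frag_hit] - f0
    spos = hit_pos[lo:hi][frag_hit]
    diags = spos - qpos
    med = np.median(diags)
    sel = diags[np.abs(diags - med) <= params.seed_diag_window]
    if sel.size == 0:
        # bimodal chance seeds can leave the median between clusters; band
        # around the cluster nearest the median instead
        nearest = diags[np.argmin(np.abs(diags - med))]
        sel = diags[np.abs(diags - nearest) <= params.seed_diag_window]
    dlo = int(sel.min()) - params.band_pad
    dhi = int(sel.max()) + params.band_pad
    res = _align.sw_banded(
        qdat.arr[f0:f1], sdat.arr, dlo, dhi,
        params.match, params.mismatch, params.gap_open, params.gap_extend,
    )
    return res


def _pair_stats(qdat: _SeqData, sdat: _SeqData, params: AniParams):
    """Accumulated (matches, alignment length, query span, n retained)."""
    if params.backend == "seeded":
        if sdat.kmer_sorted.size and qdat.sampled_kmers.size:
            idx = np.searchsorted(sdat.kmer_sorted, qdat.sampled_kmers)
            idx = np.minimum(idx, sdat.kmer_sorted.size - 1)
            hit = sdat.kmer_sorted[idx] == qdat.sampled_kmers
            hit_pos = sdat.kmer_pos[idx]
        else:
            hit = np.zeros(qdat.sampled_kmers.shape[0], dtype=bool)
            hit_pos = np.zeros(0, dtype=np.int64)
        if not hit.any():
            return 0, 0, 0, 0
    tot_matches = tot_alen = tot_span = n_ret = 0
    for f0, f1 in qdat.frags:
        flen = f1 - f0
        if params.backend == "seeded":
            res = _align_fragment_seeded(qdat, sdat, f0, f1, hit, hit_pos, params)
        else:
            res = _align.sw_full(
                qdat.arr[f0:f1], sdat.arr,
                params.match, params.mismatch, params.gap_open, params.gap_extend,
            )
        if res is None:
            continue
        score, matches, alen, qs, qe, ss, se = res
        if alen == 0:
            continue
        span = qe - qs
        if span < params.min_fragment_aln_frac * flen - 1e-9:
            continue
        if matches / alen < params.min_fragment_identity - 1e-12:
            continue
        tot_matches += matches
        tot_alen += alen
        tot_span += span
        n_ret += 1
    return tot_matches, tot_alen, tot_span, n_ret


def compute_pairwise_ani(query: str, subject: str, params: AniParams | None = None,
                         query_id: str = "query", subject_id: str = "subject") -> AniResult:
    """Fragment ANI of one ordered (query, subject) pair."""
    if params is None:
        params = AniParams()
    if len(query) == 0 or len(subject) == 0:
        raise ParameterError("both sequences must be non-empty")
    try:
        qdat = _SeqData(query, params)
    except ParameterError:
        qdat = None
    if qdat is None or not qdat.frags:
        # query too short to yield any fragment: no alignment by definition
        return AniResult(query_id, subject_id, 0.0, 0.0, 0)
    sdat = _SeqData(subject, params)
    m, alen, span, n_ret = _pair_stats(qdat, sdat, params)
    if n_ret == 0:
        return AniResult(query_id, subject_id, 0.0, 0.0, 0)
    identity = 100.0 * m / alen
    coverage = 100.0 * span / qdat.length
    return AniResult(query_id, subject_id, identity, coverage, n_ret)


@dataclass
class AniMatrix:
    """Paired asymmetric identity/coverage matrices over sequence ids.

    ``identity[i, j]`` is the percent identity with ``ids[i]`` as query and
    ``ids[j]`` as subject; the diagonal is 100 by the self-comparison
    invariant. ``coverage`` is the percent of the query aligned.
    """

    ids: list[str]
    identity: np.ndarray
    coverage: np.ndarray
    n_retained: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {x: i for i, x in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ParameterError("duplicate sequence ids in AniMatrix")
        n = len(self.ids)
        for name, mat in (("identity", self.identity), ("coverage", self.coverage)):
            if mat.shape != (n, n):
                raise ParameterError(f"{name} matrix shape {mat.shape} != ({n}, {n})")

    def get(self, query_id: str, subject_id: str) -> tuple[float, float]:
        i, j = self._index[query_id], self._index[subject_id]
        return float(self.identity[i, j]), float(self.coverage[i, j])

    def symmetrized_identity(self, a: str, b: str) -> float:
        i, j = self._index[a], self._index[b]
        return float(self.identity[i, j] + self.identity[j, i]) / 2.0

    def identity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.identity, index=self.ids, columns=self.ids)

    def coverage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coverage, index=self.ids, columns=self.ids)

    def to_tsv(self, prefix: str) -> tuple[str, str]:
        """Write ``<prefix>_identity.tsv`` and ``<prefix>_coverage.tsv``."""
        pi, pc = f"{prefix}_identity.tsv", f"{prefix}_coverage.tsv"
        self.identity_frame().to_csv(pi, sep="\t", float_format="%.10g")
        self.coverage_frame().to_csv(pc, sep="\t", float_format="%.10g")
        return pi, pc

    @classmethod
    def from_tsv(cls, identity_path, coverage_path, scale: float = 1.0) -> "AniMatrix":
        """Load a matrix pair written by :meth:`to_tsv`.

        ``scale`` multiplies the stored values; pass 100 for matrices stored
        as fractions (the convention of some ANI tools).
        """
        fi = pd.read_csv(identity_path, sep="\t", index_col=0)
        fc = pd.read_csv(coverage_path, sep="\t", index_col=0)
        ids = [str(x) for x in fi.index]
        if [str(x) for x in fi.columns] != ids:
            raise ParameterError("identity matrix row/column ids disagree")
        if [str(x) for x in fc.index] != ids or [str(x) for x in fc.columns] != ids:
            raise ParameterError("coverage matrix ids disagree with identity matrix")
        return cls(
            ids=ids,
            identity=fi.to_numpy(dtype=float) * scale,
            coverage=fc.to_numpy(dtype=float) * scale,
        )


def compute_ani_matrix(sequences, params: AniParams | None = None,
                       progress: bool = False) -> AniMatrix:
    """All-versus-all fragment ANI over a set of sequences.

    ``sequences`` is a mapping id -> sequence, a FASTA path, or an iterable
    of Biopython ``SeqRecord``s. All ordered pairs, including the diagonal,
    are computed.
    """
    if params is None:
        params = AniParams()
    seqs = _coerce_sequences(sequences)
    ids = list(seqs.keys())
    if len(ids) == 0:
        raise ParameterError("need at least one sequence")
    n = len(ids)
    data = [_SeqData(seqs[x], params) for x in ids]
    identity = np.zeros((n, n), dtype=float)
    coverage = np.zeros((n, n), dtype=float)
    n_ret = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(n):
            m, alen, span, r = _pair_stats(data[i], data[j], params)
            if r:
                identity[i, j] = 100.0 * m / alen
                coverage[i, j] = 100.0 * span / data[i].length
                n_ret[i, j] = r
        if progress:
            print(f"ani: query {i + 1}/{n} done", flush=True)
    return AniMatrix(ids=ids, identity=identity, coverage=coverage, n_retained=n_ret)


def _coerce_sequences(sequences) -> dict[str, str]:
    if isinstance(sequences, Mapping):
        out = {str(k): str(v) for k, v in sequences.items()}
    elif isinstance(sequences, (str, bytes)) or hasattr(sequences, "read"):
        from Bio import SeqIO

        out = {}
        for rec in SeqIO.parse(sequences, "fasta"):
            if rec.id in out:
                raise ParameterError(f"duplicate sequence id: {rec.id}")
            out[rec.id] = str(rec.seq)
    else:
        out = {}
        for rec in sequences:
            if rec.id in out:
                raise ParameterError(f"duplicate sequence id: {rec.id}")
            out[rec.id] = str(rec.seq)
    if len(out) == 0:
        raise ParameterError("no sequences provided")
    for k, v in out.items():
        if len(v) == 0:
            raise ParameterError(f"sequence {k} is empty")
    return out
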