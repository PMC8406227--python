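"""Pairwise sequence identity and thresholded matching against control sets.

The contamination screen hinges on a single primitive: global percent identity
between an ASV and a control sequence, with a 99% default threshold. Identity
is defined as matches divided by alignment columns, where the alignment is a
global alignment with free end gaps by default (so near-full-length amplicons
from one primer set are compared over their mutual span) and terminal-gap
columns are excluded from the denominator. The denominator is floored at the
longer sequence length, so a short exact fragment of a longer sequence never
scores highly over the overlap alone. Ambiguity codes (N etc.) always count
as mismatches.

The alignment itself is computed by Biopython's ``PairwiseAligner`` with a
custom substitution matrix implementing exactly this scoring (match +1,
mismatch −1, gap −2). A k-mer prescreen skips hopeless pairs; it is an
optimization only and never changes the result (property-tested against
exhaustive alignment).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .records import ControlCollection, SequenceRecord, Whitelist, WhitelistMode

_ALPHABET = "ACGTNRYSWKMBDHV"


@dataclass(frozen=True)
class IdentityParams:
    """Parameters of the identity computation and match thresholding.

    threshold: minimum identity fraction for a control/whitelist match.
    end_gaps_free: when True (default), terminal gaps are unpenalized and
        excluded from the identity denominator.
    kmer_prescreen_k: word size of the shared-k-mer prescreen.
    use_prescreen: disable to force exhaustive alignment of every pair.
    """

    threshold: float = 0.99
    end_gaps_free: bool = True
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0
    kmer_prescreen_k: int = 8
    use_prescreen: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValidationError(f"identity threshold {self.threshold} outside (0, 1]")
        if self.kmer_prescreen_k < 4:
            raise ValidationError("kmer_prescreen_k must be >= 4")


@dataclass(frozen=True)
class MatchEvidence:
    """Evidence that a query matched a control (or whitelist) sequence."""

    query_id: str
    control_type: str  # ntc | drill_fluid | seawater | whitelist
    control_seq_id: str
    identity: float


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap: float, end_gaps_free: bool) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            # only unambiguous self-matches score as matches; any column
            # involving an ambiguity code is a mismatch
            mat[a, b] = match if (a == b and a in "ACGT") else mismatch
    al = Align.PairwiseAligner()
    al.substitution_matrix = mat
    al.open_gap_score = gap
    al.extend_gap_score = gap
    al.mode = "global"
    if end_gaps_free:
        al.end_insertion_score = 0.0
        al.end_deletion_score = 0.0
    return al


@lru_cache(maxsize=262144)
def _identity_cached(a: str, b: str, match: float, mismatch: float, gap: float,
                     end_gaps_free: bool) -> float:
    if a == b:
        return 1.0
    al = _aligner(match, mismatch, gap, end_gaps_free)
    aln = al.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        # optimal alignment has no aligned columns (pure end gaps)
        return 0.0
    pairs = int(sum(e - s for s, e in blocks_a))
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    if end_gaps_free:
        # floor the denominator at the longer sequence length so a short
        # exact fragment of a longer sequence cannot score high over the
        # overlap alone (near-equal-length pairs are unaffected)
        columns = max(span_a + span_b - pairs, len(a), len(b))
    else:
        # include terminal gap columns in the denominator
        head = max(blocks_a[0][0], blocks_b[0][0])
        tail = max(len(a) - blocks_a[-1][1], len(b) - blocks_b[-1][1])
        columns = span_a + span_b - pairs + head + tail
    matches = 0
    for (s1, e1), (s2, _) in zip(blocks_a, blocks_b):
        for i in range(e1 - s1):
            x = a[s1 + i]
            if x == b[s2 + i] and x in "ACGT":
                matches += 1
    return matches / columns


def global_identity(a: str, b: str, params: IdentityParams = IdentityParams()) -> float:
    """Fraction of matching columns in the global (end-gaps-free) alignment.

    Symmetric by construction (arguments are canonically ordered before
    alignment), reflexive (identity of a sequence with itself is 1.0), and
    bounded in [0, 1].
    """
    if not a or not b:
        raise ValidationError("global_identity: empty sequence")
    if b < a:
        a, b = b, a
    return _identity_cached(
        a, b, params.match_score, params.mismatch_score, params.gap_score,
        params.end_gaps_free,
    )


@lru_cache(maxsize=65536)
def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def _prescreen_pass(a: str, b: str, params: IdentityParams) -> bool:
    if not params.use_prescreen:
        return True
    k = params.kmer_prescreen_k
    if len(a) < k or len(b) < k:
        return True  # too short to prescreen; fall through to alignment
    return not _kmer_set(a, k).isdisjoint(_kmer_set(b, k))


def best_control_match(
    query: SequenceRecord,
    controls: ControlCollection,
    params: IdentityParams = IdentityParams(),
) -> MatchEvidence | None:
    """Highest-identity control at or above threshold, or None.

    Ties are broken by control-type precedence (ntc > drill_fluid > seawater),
    then by lexicographically smallest control sequence id.
    """
    best: MatchEvidence | None = None
    for ctype, recs in controls.iter_sets():
        for rec in sorted(recs, key=lambda r: r.id):
            if not _prescreen_pass(query.sequence, rec.sequence, params):
                continue
            ident = global_identity(query.sequence, rec.sequence, params)
            if ident < params.threshold:
                continue
            if best is None or ident > best.identity:
                best = MatchEvidence(query.id, ctype, rec.id, ident)
    return best


def in_whitelist(
    query: SequenceRecord,
    wl: Whitelist,
    params: IdentityParams = IdentityParams(),
) -> tuple[bool, MatchEvidence | None]:
    """Whether the query is covered by the likely-indigenous whitelist.

    exact_sequence mode compares normalized sequence strings; identity_threshold
    mode requires best identity >= params.threshold; by_id mode (bare-id lists)
    checks id membership.
    """
    if wl.is_bare_ids:
        hit = query.id in wl.entries  # type: ignore[operator]
        return hit, (
            MatchEvidence(query.id, "whitelist", query.id, 1.0) if hit else None
        )
    if wl.match_mode is WhitelistMode.EXACT_SEQUENCE:
        for rec in wl.entries:  # type: ignore[union-attr]
            if rec.sequence == query.sequence:
                return True, MatchEvidence(query.id, "whitelist", rec.id, 1.0)
        return False, None
    best: MatchEvidence | None = None
    for rec in sorted(wl.entries, key=lambda r: r.id):  # type: ignore[arg-type]
        if not _prescreen_pass(query.sequence, rec.sequence, params):
            continue
        ident = global_identity(query.sequence, rec.sequence, params)
        if ident >= params.threshold and (best is None or ident > best.identity):
            best = MatchEvidence(query.id, "whitelist", rec.id, ident)
    return best is not None, best
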