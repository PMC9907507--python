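"""Global pairwise alignment and percent identity.

The comparative statistic reproduced here is percent identity under an
end-to-end (Needleman-Wunsch) alignment with linear gap costs, either over
the whole alignment or restricted to the dehydrogenase-core window spanned
by the RPLVALL...NCVN anchors of a reference sequence.  Gap columns always
count as non-identical: "completely conserved" positions are residue matches
only.

The dynamic program uses a fixed traceback tie-break (diagonal, then up,
then left) so results are reproducible to the byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .records import SequenceRecord
from .segmentation import CTD_ANCHOR, NTD_ANCHOR, AnchorMatch, find_anchor


class AlignmentInputError(ValueError):
    """Raised for empty inputs or missing window anchors."""


@dataclass
class AlignmentResult:
    """A gapped pair with score and percent identity over a column range."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    window: Optional[tuple] = None  # half-open column interval used for identity

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)
        assert 0.0 <= self.identity_pct <= 100.0


def _identity_over(aligned_a: str, aligned_b: str, start: int, stop: int) -> float:
    span = stop - start
    if span <= 0:
        raise AlignmentInputError("identity window is empty")
    matches = sum(
        1
        for x, y in zip(aligned_a[start:stop], aligned_b[start:stop])
        if x == y and x != "-"
    )
    return 100.0 * matches / span


def global_align(
    a,
    b,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignmentResult:
    """Optimal end-to-end alignment under linear gap penalty.

    Traceback prefers diagonal over up (gap in ``b``) over left (gap in
    ``a``) at score ties.  ``identity_pct`` is computed over the full
    alignment length with gap columns counted as non-identical.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else str(a)
    sb = b.residues if isinstance(b, SequenceRecord) else str(b)
    if not sa or not sb:
        raise AlignmentInputError("cannot align an empty sequence")
    n, m = len(sa), len(sb)
    score = np.empty((n + 1, m + 1), dtype=np.float64)
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    arr_a = np.frombuffer(sa.encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(sb.encode("ascii"), dtype=np.uint8)
    sub = np.where(arr_a[:, None] == arr_b[None, :], match, mismatch)
    # Row recurrence: row[j] = max(best[j-1], row[j-1] + gap) with
    # best = max(diagonal, up).  Unrolling the left dependency gives
    # row[j] = j*gap + max(row[0], max_{t<=j} (best[t-1] - t*gap)),
    # which vectorizes as a running maximum.
    js = np.arange(1, m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + gap
        best = np.maximum(diag, up)
        running = np.maximum.accumulate(best - js * gap)
        score[i, 1:] = js * gap + np.maximum(score[i, 0], running)
    # traceback with fixed tie-break: diagonal > up > left
    out_a: list = []
    out_b: list = []
    i, j = n, m
    while i > 0 or j > 0:
        here = score[i, j]
        if i > 0 and j > 0 and here == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and here == score[i - 1, j] + gap:
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score[n, m]),
        identity_pct=_identity_over(aligned_a, aligned_b, 0, len(aligned_a)),
    )


def window_identity(
    a,
    b,
    start_motif: str = NTD_ANCHOR,
    end_motif: str = CTD_ANCHOR,
    max_mismatch: int = 1,
    **align_kwargs,
) -> AlignmentResult:
    """Percent identity over the anchored core window of reference ``a``.

    The pair is globally aligned in full, then identity is restricted to the
    alignment columns spanned by ``a``'s window from the start of
    ``start_motif`` through the end of ``end_motif`` (both motifs included).
    Gap columns inside the window count as mismatches.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else str(a)
    start_hit = find_anchor(sa, start_motif, max_mismatch)
    if not isinstance(start_hit, AnchorMatch):
        raise AlignmentInputError(f"reference lacks the {start_motif!r} anchor")
    tail_hit = find_anchor(sa[start_hit.start:], end_motif, max_mismatch)
    if not isinstance(tail_hit, AnchorMatch):
        raise AlignmentInputError(f"reference lacks the {end_motif!r} anchor")
    win_lo = start_hit.start
    win_hi = start_hit.start + tail_hit.end  # exclusive, in reference coordinates
    result = global_align(a, b, **align_kwargs)
    # map reference residue positions to alignment columns
    cols = []
    pos = 0
    for col, ch in enumerate(result.aligned_a):
        if ch != "-":
            if win_lo <= pos < win_hi:
                cols.append(col)
            pos += 1
    col_lo, col_hi = cols[0], cols[-1] + 1
    identity = _identity_over(result.aligned_a, result.aligned_b, col_lo, col_hi)
    return AlignmentResult(
        aligned_a=result.aligned_a,
        aligned_b=result.aligned_b,
        score=result.score,
        identity_pct=identity,
        window=(col_lo, col_hi),
    )
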