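"""miORF annotation relative to the pre-miR hairpin.

A pri-miR's candidate miORF is the longest ORF lying wholly 5' of the
pre-miR interval (ties broken 5'-most).  The module also enumerates
downstream in-frame alternative starts (ATG1/ATG2), scores the initiation
context against a configurable consensus matrix, and applies single-base
variants (e.g. a natural premature-stop polymorphism) with full
re-annotation, reporting C-terminal truncations.

The context score is a heuristic annotation: favorability of a natural
context is ultimately an experimental property, so the score is a weighted
consensus match, clearly labeled as such in output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from .orfscan import OrfHit, find_orfs

# Cavener-style Drosophila initiation consensus (C/A)AA(A/C)ATG G.
# Offsets are relative to the A of ATG; -3 carries the highest weight.
DEFAULT_CONTEXT_PWM: dict[int, tuple[frozenset[str], float]] = {
    -4: (frozenset("AC"), 1.0),
    -3: (frozenset("AC"), 2.0),
    -2: (frozenset("A"), 1.0),
    -1: (frozenset("AC"), 1.0),
    3: (frozenset("G"), 1.0),  # the +4 base, first after the ATG
}


class ContextScore(NamedTuple):
    score: float
    favorable: bool
    truncated: bool


@dataclass(frozen=True)
class MiOrfCandidate:
    """A candidate miORF: the selected upstream ORF plus context annotation.

    ``alt_starts`` lists downstream in-frame ATGs sharing the stop as
    (start_rank, aa_len), aa_len strictly decreasing with rank.
    """

    transcript_id: str
    orf: OrfHit
    upstream_of_premir: bool
    is_longest_upstream: bool
    alt_starts: tuple[tuple[int, int], ...]
    context_score: float
    context_favorable: bool


@dataclass(frozen=True)
class VariantSpec:
    """A single-base substitution in transcript coordinates (0-based)."""

    transcript_id: str
    position: int
    ref_base: str
    alt_base: str


def context_score(
    sequence: str,
    atg_pos: int,
    pwm: Optional[dict[int, tuple[frozenset[str], float]]] = None,
    threshold: float = 0.5,
) -> ContextScore:
    """Score the initiation context of the ATG at ``atg_pos``.

    The score is the weight-normalized fraction of scored positions
    (default -4..-1 and +4) matching the consensus.  ``favorable`` requires
    score >= threshold AND the -3 base in the consensus's preferred set.
    Windows truncated by a transcript end are scored over the available
    positions and flagged.
    """
    seq = sequence.upper()
    if pwm is None:
        pwm = DEFAULT_CONTEXT_PWM
    if seq[atg_pos : atg_pos + 3] != "ATG":
        raise ValueError(f"no ATG at position {atg_pos}")
    total_w = 0.0
    matched_w = 0.0
    truncated = False
    minus3_ok = True
    any_scored = False
    for offset, (preferred, weight) in pwm.items():
        pos = atg_pos + offset
        if pos < 0 or pos >= len(seq):
            truncated = True
            if offset == -3:
                minus3_ok = False
            continue
        any_scored = True
        total_w += weight
        hit = seq[pos] in preferred
        if hit:
            matched_w += weight
        if offset == -3:
            minus3_ok = hit
    if not any_scored:
        raise ValueError("context window entirely outside sequence")
    score = matched_w / total_w
    return ContextScore(score, score >= threshold and minus3_ok, truncated)


def select_miorf(
    transcript,
    min_aa: int = 10,
    mode: str = "maximal",
    pwm=None,
    context_threshold: float = 0.5,
) -> Optional[MiOrfCandidate]:
    """Select the candidate miORF of a pri-miR transcript.

    Among ORFs wholly 5' of the pre-miR (stop codon ending at or before the
    pre-miR start), returns the longest; equal lengths break 5'-most.
    Returns None when no ORF qualifies.
    """
    if transcript.rna_class != "pri_miR":
        raise ValueError(f"{transcript.id}: not a pri_miR transcript")
    if transcript.premir_interval is None:
        raise ValueError(f"{transcript.id}: missing premir_interval")
    premir_start = transcript.premir_interval[0]
    # 'all' mode so alternative starts sharing the stop are in hand
    all_hits = find_orfs(transcript.sequence, min_aa=min_aa, mode="all",
                         transcript_id=transcript.id)
    upstream = [h for h in all_hits if h.end_nt <= premir_start]
    primaries = upstream if mode == "all" else [h for h in upstream if h.start_rank == 1]
    if not primaries:
        return None
    best = max(primaries, key=lambda h: (h.aa_len, -h.start_nt))
    alts = tuple(
        (h.start_rank, h.aa_len)
        for h in sorted(upstream, key=lambda h: h.start_rank)
        if h.frame == best.frame and h.end_nt == best.end_nt and h.start_rank > best.start_rank
    )
    ctx = context_score(transcript.sequence, best.start_nt, pwm=pwm,
                        threshold=context_threshold)
    return MiOrfCandidate(
        transcript_id=transcript.id,
        orf=best,
        upstream_of_premir=True,
        is_longest_upstream=True,
        alt_starts=alts,
        context_score=ctx.score,
        context_favorable=ctx.favorable,
    )


def apply_variant(transcript, variant: VariantSpec):
    """Apply a single-base substitution, returning a new transcript record.

    The reference base must match the sequence at the variant position;
    downstream annotation must be recomputed on the returned record.
    """
    seq = transcript.sequence
    if not (0 <= variant.position < len(seq)):
        raise ValueError(f"variant position {variant.position} outside transcript")
    observed = seq[variant.position]
    if observed != variant.ref_base.upper():
        raise ValueError(
            f"ref mismatch at {variant.position}: expected {variant.ref_base}, "
            f"observed {observed}"
        )
    new_seq = seq[: variant.position] + variant.alt_base.upper() + seq[variant.position + 1 :]
    return replace(transcript, sequence=new_seq)


def truncation_report(before: MiOrfCandidate, after: Optional[MiOrfCandidate]) -> dict:
    """Classify the effect of a variant by comparing pre/post candidates.

    Same-start candidates report the C-terminal truncation length
    (aa before - aa after); a changed or lost start reports 'start_lost' /
    'candidate_lost'; identical ORFs report 'unchanged'.
    """
    if after is None:
        return {"effect": "candidate_lost"}
    if after.orf.start_nt != before.orf.start_nt or after.orf.frame != before.orf.frame:
        return {"effect": "start_lost"}
    delta = before.orf.aa_len - after.orf.aa_len
    if delta == 0:
        return {"effect": "unchanged", "aa_len": before.orf.aa_len}
    return {
        "effect": "truncation",
        "aa_len_before": before.orf.aa_len,
        "aa_len_after": after.orf.aa_len,
        "truncation_aa": delta,
    }


def annotate_all(
    transcripts: Sequence,
    peptide_matches: Optional[Sequence] = None,
    min_aa: int = 10,
    mode: str = "maximal",
) -> pd.DataFrame:
    """Annotate every pri-miR transcript: one row each, with the candidate
    miORF (if any), context fields, and the count of peptide matches
    overlapping the candidate's nucleotide interval."""
    rows = []
    for t in transcripts:
        if t.rna_class != "pri_miR":
            continue
        cand = select_miorf(t, min_aa=min_aa, mode=mode)
        row: dict = {"transcript_id": t.id, "has_candidate": cand is not None}
        if cand is None:
            row.update(
                start_nt=pd.NA, end_nt=pd.NA, aa_len=pd.NA, frame=pd.NA,
                n_alt_starts=pd.NA, context_score=pd.NA,
                context_favorable=pd.NA, n_peptide_matches=0,
            )
        else:
            s, e = cand.orf.start_nt, cand.orf.end_nt
            n_ev = 0
            if peptide_matches is not None:
                for m in peptide_matches:
                    if m.transcript_id != t.id:
                        continue
                    ms, me = m.nt_interval
                    if ms < e and s < me:
                        n_ev += 1
            row.update(
                start_nt=s, end_nt=e, aa_len=cand.orf.aa_len, frame=cand.orf.frame,
                n_alt_starts=len(cand.alt_starts), context_score=cand.context_score,
                context_favorable=cand.context_favorable, n_peptide_matches=n_ev,
            )
        rows.append(row)
    cols = ["transcript_id", "has_candidate", "start_nt", "end_nt", "aa_len",
            "frame", "n_alt_starts", "context_score", "context_favorable",
            "n_peptide_matches"]
    return pd.DataFrame(rows, columns=cols)
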