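"""Three-frame translation and exact peptide matching.

Locates ribosome-profiling-derived sORF-encoded peptides inside the
forward-strand three-frame translations of transcripts.  Matching is exact
substring containment (case-insensitive), restricted to stop-free segments
of a translation: a peptide spanning a stop codon cannot be a single
translation product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._codon import CODON_TABLE

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of a transcript: the full peptide string with '*'
    at stop codons, plus its maximal stop-free segments as (aa_offset, seq)."""

    transcript_id: str
    frame: int
    peptide_string: str
    segments: tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class PeptideMatch:
    """One occurrence of a peptide inside a frame translation.

    ``aa_offset`` is 0-based in the frame translation; ``nt_interval`` is
    the corresponding half-open transcript interval
    [frame + 3*aa_offset, frame + 3*(aa_offset + len(peptide))).
    """

    peptide_id: str
    peptide: str
    transcript_id: str
    frame: int
    aa_offset: int

    @property
    def nt_interval(self) -> tuple[int, int]:
        start = self.frame + 3 * self.aa_offset
        return (start, start + 3 * len(self.peptide))


def _segments(peptide_string: str) -> tuple[tuple[int, str], ...]:
    segs = []
    offset = 0
    for part in peptide_string.split("*"):
        if part:
            segs.append((offset, part))
        offset += len(part) + 1
    return tuple(segs)


def translate3(sequence: str, transcript_id: str = "") -> list[FrameTranslation]:
    """Translate all three forward frames under the standard nuclear code.

    Codons containing N translate to 'X'; stops render as '*'.  Sequences
    shorter than 3 nt yield empty translations with a warning.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        logger.warning("sequence %r shorter than one codon; empty translations", transcript_id)
        return [FrameTranslation(transcript_id, f, "", ()) for f in range(3)]
    out = []
    for frame in range(3):
        aa = "".join(
            CODON_TABLE.get(seq[i : i + 3], "X")
            for i in range(frame, len(seq) - 2, 3)
        )
        out.append(FrameTranslation(transcript_id, frame, aa, _segments(aa)))
    return out


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return
        yield idx
        start = idx + 1


def match_peptides(
    translations: Sequence[FrameTranslation],
    peptides: Sequence[tuple[str, str]],
    min_len: int = 7,
) -> list[PeptideMatch]:
    """Locate every occurrence of each peptide within stop-free segments.

    ``peptides`` is a sequence of (peptide_id, sequence) pairs.  Peptides
    shorter than ``min_len`` are dropped; peptides with characters outside
    the amino-acid alphabet (20 residues + X) are rejected with a logged
    count.  Output order is deterministic:
    (transcript_id, frame, aa_offset, peptide_id).
    """
    clean: list[tuple[str, str]] = []
    n_bad = 0
    for pid, pep in peptides:
        pep_u = pep.upper()
        if not set(pep_u) <= AA_ALPHABET:
            n_bad += 1
            continue
        if len(pep_u) >= min_len:
            clean.append((pid, pep_u))
    if n_bad:
        logger.warning("rejected %d peptide(s) with non-amino-acid characters", n_bad)

    matches = []
    for tr in translations:
        for seg_offset, seg in tr.segments:
            for pid, pep in clean:
                for idx in _find_all(seg, pep):
                    matches.append(
                        PeptideMatch(pid, pep, tr.transcript_id, tr.frame, seg_offset + idx)
                    )
    matches.sort(key=lambda m: (m.transcript_id, m.frame, m.aa_offset, m.peptide_id))
    return matches


def summarize_by_primir(
    matches: Sequence[PeptideMatch], transcripts
) -> tuple[pd.DataFrame, dict]:
    """Per-pri-miR match counts and a global summary.

    Counts are restricted to transcripts with ``rna_class == "pri_miR"``;
    pri-miRs with no match are reported with zero.  In the global summary a
    peptide hitting several pri-miRs is counted once in
    ``n_peptides_matched`` but once per transcript in the per-pri-miR rows
    (both numbers reported to avoid ambiguity).
    """
    primirs = [t for t in transcripts if t.rna_class == "pri_miR"]
    primir_ids = {t.id for t in primirs}
    per: dict[str, set[str]] = {t.id: set() for t in primirs}
    matched_peptides: set[str] = set()
    for m in matches:
        if m.transcript_id in primir_ids:
            per[m.transcript_id].add(m.peptide_id)
            matched_peptides.add(m.peptide_id)
    table = pd.DataFrame(
        {
            "transcript_id": list(per),
            "n_peptides": [len(v) for v in per.values()],
        }
    ).sort_values("transcript_id", ignore_index=True)
    summary = {
        "n_primirs_with_match": int((table["n_peptides"] > 0).sum()),
        "n_peptides_matched": len(matched_peptides),
        "n_peptide_hits_total": int(table["n_peptides"].sum()),
    }
    return table, summary
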