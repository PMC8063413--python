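"""Short ORF enumeration and per-class density comparison.

An sORF here is an ATG-initiated open reading frame on the forward strand
of a mature transcript, read to the first in-frame stop codon, encoding at
least ``min_aa`` residues (default 10, stop excluded).  Densities are
expressed as ORFs per kilobase of transcript and compared across RNA
classes (CDS, UTRs, lncRNA, pri-miR) as distributions, box-plot style:
Kruskal-Wallis globally, pairwise Mann-Whitney with Bonferroni correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._codon import CODON_TABLE

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
VALID_BASES = frozenset("ACGTN")

Mode = Literal["maximal", "all"]


@dataclass(frozen=True)
class OrfHit:
    """One ATG-initiated ORF ending at its first in-frame stop.

    Coordinates are 0-based half-open on the transcript: ``start_nt`` is
    the A of the ATG, ``end_nt`` is just past the stop codon.  ``start_rank``
    ranks the initiating ATG among in-frame ATGs sharing this stop
    (1 = 5'-most, the maximal ORF).
    """

    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int
    aa_len: int
    peptide: str
    start_rank: int
    has_stop: bool = True

    @property
    def is_maximal(self) -> bool:
        return self.start_rank == 1

    def __post_init__(self) -> None:
        if (self.end_nt - self.start_nt) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        expected = (self.end_nt - self.start_nt) // 3 - (1 if self.has_stop else 0)
        if self.aa_len != expected:
            raise ValueError("aa_len inconsistent with coordinates")


@dataclass(frozen=True)
class DensityRecord:
    """Per-transcript sORF density (ORFs per kb)."""

    transcript_id: str
    rna_class: str
    n_orfs: int
    length_kb: float

    @property
    def orfs_per_kb(self) -> float:
        return self.n_orfs / self.length_kb


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    for i, base in enumerate(seq):
        if base not in VALID_BASES:
            raise ValueError(f"invalid base {base!r} at offset {i}")
    return seq


def _translate_codons(seq: str, start: int, end: int) -> str:
    return "".join(
        CODON_TABLE.get(seq[i : i + 3], "X") for i in range(start, end, 3)
    )


def find_orfs(
    sequence: str,
    min_aa: int = 10,
    mode: Mode = "maximal",
    transcript_id: str = "",
    allow_open: bool = False,
) -> list[OrfHit]:
    """Enumerate forward-strand ORFs in all three frames.

    Each ORF runs from an ATG to the first in-frame stop.  ``mode="maximal"``
    keeps only the 5'-most ATG per (frame, stop); ``mode="all"`` keeps every
    qualifying ATG.  Codons containing N never act as start or stop.
    ``allow_open`` additionally reports stop-less ORFs running off the 3'
    end (off by default: a complete ORF codes to a stop).

    Hits are sorted by (start_nt, frame).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if mode not in ("maximal", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    seq = _validate_sequence(sequence)
    hits: list[OrfHit] = []
    n = len(seq)
    for frame in range(3):
        open_starts: list[int] = []  # ATG positions awaiting a stop
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "ATG":
                open_starts.append(pos)
            elif codon in STOP_CODONS:
                end_nt = pos + 3
                for rank, start_nt in enumerate(open_starts, start=1):
                    aa_len = (end_nt - start_nt) // 3 - 1
                    if aa_len < min_aa:
                        continue
                    if mode == "maximal" and rank > 1:
                        continue
                    peptide = _translate_codons(seq, start_nt, end_nt - 3)
                    hits.append(
                        OrfHit(transcript_id, frame, start_nt, end_nt, aa_len, peptide, rank)
                    )
                open_starts = []
        if allow_open and open_starts:
            # stop-less ORFs truncated by the transcript 3' end
            end_nt = frame + 3 * ((n - frame) // 3)
            for rank, start_nt in enumerate(open_starts, start=1):
                aa_len = (end_nt - start_nt) // 3
                if aa_len < min_aa or (mode == "maximal" and rank > 1):
                    continue
                peptide = _translate_codons(seq, start_nt, end_nt)
                hits.append(
                    OrfHit(
                        transcript_id, frame, start_nt, end_nt, aa_len,
                        peptide, rank, has_stop=False,
                    )
                )
    hits.sort(key=lambda h: (h.start_nt, h.frame))
    return hits


def density(transcript, min_aa: int = 10, mode: Mode = "maximal") -> DensityRecord:
    """Compute the per-transcript ORF density record for one transcript.

    ``transcript`` is any object with ``id``, ``rna_class`` and ``sequence``
    attributes (a :class:`~mipepscan.synthio.TranscriptRecord` in practice).
    """
    seq = transcript.sequence
    if len(seq) == 0:
        raise ValueError("transcript length must be > 0")
    n_orfs = len(find_orfs(seq, min_aa=min_aa, mode=mode, transcript_id=transcript.id))
    return DensityRecord(transcript.id, transcript.rna_class, n_orfs, len(seq) / 1000.0)


@dataclass
class ClassComparison:
    """Cross-class density comparison: summaries, global and pairwise tests."""

    summary: pd.DataFrame           # per class: n, median, q1, q3
    kruskal_stat: float
    kruskal_p: float
    pairwise: pd.DataFrame          # class_a, class_b, u_stat, p_raw, p_bonferroni
    ranking: list[str] = field(default_factory=list)  # classes by descending median


def compare_classes(densities: Iterable[DensityRecord]) -> ClassComparison:
    """Kruskal-Wallis across RNA classes plus Bonferroni-corrected pairwise
    Mann-Whitney tests on per-transcript ORFs/kb.

    Classes with fewer than two records are excluded with a warning.  When
    every observation is identical (degenerate all-ties case) p-values are
    reported as 1.0.
    """
    by_class: dict[str, list[float]] = {}
    for rec in densities:
        by_class.setdefault(rec.rna_class, []).append(rec.orfs_per_kb)
    kept = {}
    for cls, vals in by_class.items():
        if len(vals) < 2:
            logger.warning("class %s has <2 records; excluded from comparison", cls)
            continue
        kept[cls] = np.asarray(vals, dtype=float)
    if len(kept) < 2:
        raise ValueError("need >=2 classes with >=2 records each")

    rows = [
        {
            "rna_class": cls,
            "n": len(v),
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
        }
        for cls, v in kept.items()
    ]
    summary = pd.DataFrame(rows).set_index("rna_class")
    ranking = list(summary.sort_values("median", ascending=False).index)

    groups = list(kept.values())
    all_vals = np.concatenate(groups)
    if np.all(all_vals == all_vals[0]):
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = stats.kruskal(*groups)

    pair_rows = []
    pairs = list(combinations(sorted(kept), 2))
    m = len(pairs)
    for a, b in pairs:
        va, vb = kept[a], kept[b]
        joined = np.concatenate([va, vb])
        if np.all(joined == joined[0]):
            u, p = len(va) * len(vb) / 2.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        pair_rows.append(
            {
                "class_a": a,
                "class_b": b,
                "u_stat": float(u),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * m)),
            }
        )
    pairwise = pd.DataFrame(pair_rows)
    return ClassComparison(summary, float(kw_stat), float(kw_p), pairwise, ranking)
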