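"""Descriptive analyses of a curated NS dataset.

Three characterisations of a labeled homo-oligomer collection:

* the NS label distribution, overall or per organism (homodimers and
  monomers dominate Swiss-Prot-derived sets, with even stoichiometries
  more common than odd);
* NS diversity within each EC number — how many distinct oligomeric
  states the proteins sharing one catalytic activity adopt;
* pairwise sequence identity of proteins sharing an EC number, split by
  whether their NS labels agree, to quantify how far sequence similarity
  alone predicts stoichiometry.

Identity is computed from Needleman-Wunsch global alignments (BLOSUM62,
gap open 10 / extend 0.5) as matches / alignment length, gaps included.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from deepsub.curation import LabeledProtein

logger = logging.getLogger(__name__)


@dataclass
class ECGroup:
    ec_number: str
    members: list[str]
    ns_labels: set[int]

    @property
    def diversity(self) -> int:
        return len(self.ns_labels)


@dataclass
class PairIdentityRecord:
    accession_a: str
    accession_b: str
    shared_ec: str
    percent_identity: float
    label_match: bool


def label_distribution(
    dataset: Sequence[LabeledProtein], by_organism: bool = False
) -> pd.Series | pd.DataFrame:
    """Counts per NS label; with ``by_organism`` a label x organism table."""
    if not dataset:
        return (
            pd.DataFrame(dtype=int)
            if by_organism
            else pd.Series(dtype=int, name="count")
        )
    df = pd.DataFrame(
        {"ns_label": [r.ns_label for r in dataset], "organism": [r.organism for r in dataset]}
    )
    if by_organism:
        return df.groupby(["organism", "ns_label"]).size().unstack(fill_value=0)
    counts = df["ns_label"].value_counts().sort_index()
    counts.name = "count"
    return counts


def ec_ns_diversity(
    dataset: Sequence[LabeledProtein],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-EC NS diversity table and the histogram of diversity values.

    Proteins without an EC number are ignored; a protein carrying several
    EC numbers contributes to each. The table has one row per distinct
    EC: protein count and the sorted label set, ordered by diversity
    (most diverse first), matching the usual report shape.
    """
    groups: dict[str, ECGroup] = {}
    for rec in dataset:
        for ec in rec.ec_numbers:
            grp = groups.setdefault(ec, ECGroup(ec, [], set()))
            grp.members.append(rec.accession)
            grp.ns_labels.add(rec.ns_label)
    rows = [
        {
            "ec_number": g.ec_number,
            "protein_count": len(g.members),
            "subunit_labels": ", ".join(str(v) for v in sorted(g.ns_labels)),
            "diversity": g.diversity,
        }
        for g in groups.values()
    ]
    table = pd.DataFrame(rows, columns=["ec_number", "protein_count", "subunit_labels", "diversity"])
    if len(table):
        table = table.sort_values(
            ["diversity", "protein_count"], ascending=[False, False]
        ).reset_index(drop=True)
        histogram = table["diversity"].value_counts().sort_index()
    else:
        histogram = pd.Series(dtype=int)
    histogram.name = "n_ec_numbers"
    return table, histogram


def _make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def percent_identity(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Global-alignment percent identity: matches / alignment length * 100.

    Gap columns count toward the alignment length. Symmetric in the two
    sequences; identity of a sequence with itself is 100.
    """
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length


def pairwise_identity(
    dataset: Sequence[LabeledProtein],
    max_pairs: int = 1000,
    seed: int = 0,
    aligner: Align.PairwiseAligner | None = None,
) -> list[PairIdentityRecord]:
    """Percent identity for (sampled) protein pairs sharing an EC number.

    All unordered pairs sharing at least one EC are enumerated; if more
    than ``max_pairs`` exist, a seeded uniform subsample is aligned
    (all-vs-all within large EC groups is quadratic). Pairs whose
    sequences contain residues outside the substitution matrix alphabet
    are skipped with a warning.
    """
    if aligner is None:
        aligner = _make_aligner()
    by_ec: dict[str, list[LabeledProtein]] = {}
    for rec in dataset:
        for ec in rec.ec_numbers:
            by_ec.setdefault(ec, []).append(rec)
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[LabeledProtein, LabeledProtein, str]] = []
    for ec in sorted(by_ec):
        for a, b in itertools.combinations(by_ec[ec], 2):
            key = tuple(sorted((a.accession, b.accession)))
            if key not in seen:
                seen.add(key)
                pairs.append((a, b, ec))
    if len(pairs) > max_pairs:
        rng = np.random.Generator(np.random.PCG64(seed))
        chosen = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(chosen)]
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    records: list[PairIdentityRecord] = []
    for a, b, ec in pairs:
        bad = (set(a.sequence) | set(b.sequence)) - alphabet
        if bad:
            logger.warning(
                "skipping pair %s/%s: residues %s not in the substitution matrix",
                a.accession, b.accession, sorted(bad),
            )
            continue
        records.append(
            PairIdentityRecord(
                accession_a=a.accession,
                accession_b=b.accession,
                shared_ec=ec,
                percent_identity=percent_identity(a.sequence, b.sequence, aligner),
                label_match=a.ns_label == b.ns_label,
            )
        )
    return records


def identity_records_frame(records: Iterable[PairIdentityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession_a": r.accession_a,
                "accession_b": r.accession_b,
                "shared_ec": r.shared_ec,
                "percent_identity": r.percent_identity,
                "label_match": r.label_match,
            }
            for r in records
        ],
        columns=["accession_a", "accession_b", "shared_ec", "percent_identity", "label_match"],
    )
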