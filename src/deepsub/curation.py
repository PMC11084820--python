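"""Mine number-of-subunits (NS) labels from UniProt-style XML.

Swiss-Prot entries carry a free-text "subunit" comment describing the
oligomeric state of the protein ("Monomer.", "Homodimer.",
"Homooctamer of 4 homodimers; disulfide-linked." ...). This module
stream-parses the XML dialect, discards entries whose annotation is
inferred rather than observed (the ECO:0000250 sequence-similarity
evidence code, or hedging qualifiers such as "By similarity"), and maps
the surviving descriptions to one of ten NS labels
{1, 2, 3, 4, 5, 6, 7, 8, 10, 12} through a priority keyword-rule table.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import BinaryIO, Iterable, Iterator

import yaml
from lxml import etree

logger = logging.getLogger(__name__)

#: The ten admissible NS labels (no 9 or 11: Swiss-Prot essentially never
#: documents those homo-oligomeric states).
VALID_NS_LABELS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12)

#: Amino-acid alphabet accepted in sequences: the 20 canonical residues
#: plus ambiguity codes B/Z/X and the rare translated residues U/O.
SEQUENCE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZUO")

_ECO_PATTERN = re.compile(r"^ECO:\d{7}$")

#: Hedging qualifiers whose presence in the subunit text marks the
#: annotation as inferred rather than experimentally observed.
QUALIFIER_STRINGS = ("By similarity", "Probable", "Potential")

#: Evidence code for "inferred from sequence similarity, manual assertion".
SIMILARITY_EVIDENCE = "ECO:0000250"

# Discard reasons, in the order they are tested.
REASON_NO_SUBUNIT = "no-subunit-description"
REASON_SIMILARITY = "similarity-evidence"
REASON_QUALIFIER = "qualifier"
REASON_UNLABELED = "unlabeled"
REASON_FRAGMENT = "fragment"


@dataclass
class UniProtEntry:
    """One parsed database record."""

    accession: str
    sequence: str
    protein_name: str = ""
    organism: str = ""
    ec_numbers: list[str] = field(default_factory=list)
    subunit_text: str = ""
    evidence_codes: list[str] = field(default_factory=list)
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(f"illegal residues in sequence of {self.accession}: {sorted(bad)}")
        for code in self.evidence_codes:
            if not _ECO_PATTERN.match(code):
                raise ValueError(f"malformed evidence code {code!r}")


@dataclass(frozen=True)
class KeywordRule:
    """One row of the keyword -> NS mapping.

    Compound rules ("homooctamer of" ...) identify the outermost assembly
    of a nested description and are applied before base keywords.
    """

    pattern: str
    label: int
    priority: int
    compound: bool = False

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("rule pattern must be non-empty")
        if self.label not in VALID_NS_LABELS:
            raise ValueError(f"label {self.label} not in {VALID_NS_LABELS}")


@dataclass
class LabeledProtein:
    """A sequence with its NS label and the provenance of the match."""

    accession: str
    sequence: str
    ns_label: int
    matched_rule: str
    ec_numbers: list[str] = field(default_factory=list)
    organism: str = ""

    def __post_init__(self) -> None:
        if self.ns_label not in VALID_NS_LABELS:
            raise ValueError(f"ns_label {self.ns_label} not in {VALID_NS_LABELS}")


@dataclass
class CurationReport:
    """Per-reason discard counts; conservation: parsed = retained + discarded."""

    n_parsed: int = 0
    n_retained: int = 0
    discards: dict[str, int] = field(default_factory=dict)

    def discard(self, reason: str) -> None:
        self.discards[reason] = self.discards.get(reason, 0) + 1

    @property
    def n_discarded(self) -> int:
        return sum(self.discards.values())


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _entry_to_record(elem: etree._Element) -> UniProtEntry | None:
    """Extract one UniProtEntry from an ``<entry>`` element, or None if the
    entry lacks an accession or sequence."""
    accession = ""
    protein_name = ""
    organism = ""
    sequence = ""
    is_fragment = False
    ec_numbers: list[str] = []
    subunit_text = ""
    evidence_attr = ""
    evidence_keys: dict[str, str] = {}

    for child in elem.iter():
        tag = _localname(child.tag)
        if tag == "accession" and not accession:
            accession = (child.text or "").strip()
        elif tag == "fullName" and not protein_name:
            protein_name = (child.text or "").strip()
        elif tag == "name" and _localname(child.getparent().tag) == "organism":
            if child.get("type") == "scientific" and not organism:
                organism = (child.text or "").strip()
        elif tag == "ecNumber":
            text = (child.text or "").strip()
            if text and text not in ec_numbers:
                ec_numbers.append(text)
        elif tag == "comment" and child.get("type") == "subunit":
            for sub in child:
                if _localname(sub.tag) == "text":
                    subunit_text = (sub.text or "").strip()
                    evidence_attr = sub.get("evidence", "") or child.get("evidence", "")
            if not subunit_text and (child.text or "").strip():
                # dialect without a nested <text> element
                subunit_text = child.text.strip()
                evidence_attr = child.get("evidence", "")
        elif tag == "evidence":
            key = child.get("key")
            eco = child.get("type", "")
            if key and eco:
                evidence_keys[key] = eco
        elif tag == "sequence":
            sequence = re.sub(r"\s+", "", child.text or "")
            is_fragment = child.get("fragment") is not None

    if not accession or not sequence:
        logger.warning("skipping entry lacking accession or sequence (accession=%r)", accession)
        return None

    # The evidence attribute holds either integer keys referencing
    # <evidence key=... type="ECO:..."/> declarations, or (in terse
    # dialects) the ECO codes directly.
    evidence_codes: list[str] = []
    for token in evidence_attr.split():
        code = token if token.startswith("ECO:") else evidence_keys.get(token, "")
        if code and code not in evidence_codes:
            evidence_codes.append(code)

    return UniProtEntry(
        accession=accession,
        sequence=sequence,
        protein_name=protein_name,
        organism=organism,
        ec_numbers=ec_numbers,
        subunit_text=subunit_text,
        evidence_codes=evidence_codes,
        is_fragment=is_fragment,
    )


def _open_source(source: str | Path | BinaryIO | bytes) -> BinaryIO:
    if isinstance(source, bytes):
        return io.BytesIO(source)
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return gzip.open(path, "rb")  # type: ignore[return-value]
        return open(path, "rb")
    return source


def parse_uniprot_xml(source: str | Path | BinaryIO | bytes) -> Iterator[UniProtEntry]:
    """Stream-parse UniProt-dialect XML into :class:`UniProtEntry` records.

    Memory use is bounded independently of file size: each ``<entry>``
    element is cleared after it is converted, so arbitrarily large files
    parse in constant memory. Both namespaced and namespace-free
    documents are accepted; entries lacking an accession or a sequence
    are skipped with a logged warning.

    Raises
    ------
    etree.XMLSyntaxError
        On malformed XML, with the failing line/column position.
    """
    stream = _open_source(source)
    try:
        context = etree.iterparse(stream, events=("end",))
        for _event, elem in context:
            if _localname(elem.tag) != "entry":
                continue
            record = _entry_to_record(elem)
            if record is not None:
                yield record
            # release processed elements to bound memory
            elem.clear()
            parent = elem.getparent()
            if parent is not None:
                while elem.getprevious() is not None:
                    del parent[0]
        del context
    finally:
        if stream is not source:
            stream.close()


def filter_evidence(entry: UniProtEntry) -> tuple[bool, str | None]:
    """Decide whether an entry's subunit annotation is trustworthy.

    Returns ``(retain, reason)``. An entry is discarded iff (a) it has no
    subunit description, (b) the comment's evidence includes ECO:0000250
    (inferred from sequence similarity), or (c) the description carries a
    hedging qualifier ("By similarity", "Probable", "Potential"). The
    first matching reason, in that order, is reported.
    """
    if not entry.subunit_text:
        return False, REASON_NO_SUBUNIT
    if SIMILARITY_EVIDENCE in entry.evidence_codes:
        return False, REASON_SIMILARITY
    if any(q in entry.subunit_text for q in QUALIFIER_STRINGS):
        return False, REASON_QUALIFIER
    return True, None


def _check_rules(rules: Iterable[KeywordRule]) -> list[KeywordRule]:
    rules = list(rules)
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule table has duplicate priorities")
    return sorted(rules, key=lambda r: r.priority)


def _normalise(text: str) -> str:
    # fold hyphenated spellings such as "Homo-dodecamer"
    return re.sub(r"(?i)homo-", "homo", text)


def _word_regex(pattern: str) -> re.Pattern[str]:
    # whole-word, case-insensitive; oligomer terms tolerate a plural "s"
    parts = []
    for word in pattern.split():
        esc = re.escape(word)
        if len(word) > 3:
            esc += "s?"
        parts.append(esc)
    return re.compile(r"\b" + r"\s+".join(parts) + r"\b", re.IGNORECASE)


def assign_label(subunit_text: str, rules: Iterable[KeywordRule]) -> int | None:
    """Map a subunit description to an NS label, or None if unlabeled.

    Compound rules are tested first, in priority order, and decide the
    label immediately: "Homooctamer of 4 homodimers" is an octamer built
    from dimers, so the "homooctamer of" phrase wins. Otherwise the label
    is assigned only when exactly one distinct base keyword occurs;
    ambiguous descriptions naming several oligomeric states ("Homodimer;
    can also form homotetramers.") are left unlabeled to keep false
    positives out of the dataset. Matching is case-insensitive on whole
    words.
    """
    ordered = _check_rules(rules)
    text = _normalise(subunit_text)
    for rule in ordered:
        if rule.compound and _word_regex(rule.pattern).search(text):
            return rule.label
    hits: dict[str, int] = {}
    for rule in ordered:
        if not rule.compound and _word_regex(rule.pattern).search(text):
            hits[rule.pattern] = rule.label
    if len(hits) == 1:
        return next(iter(hits.values()))
    return None


def _rules_from_mappings(rows: Iterable[dict]) -> list[KeywordRule]:
    return _check_rules(
        KeywordRule(
            pattern=str(row["pattern"]),
            label=int(row["label"]),
            priority=int(row["priority"]),
            compound=bool(row.get("compound", False)),
        )
        for row in rows
    )


def load_rules(path: str | Path) -> list[KeywordRule]:
    """Load a rule table from YAML (``rules:`` list) or TSV with columns
    pattern, label, priority, compound."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return _rules_from_mappings(doc["rules"])
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if line.strip():
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    for row in rows:
        row["compound"] = str(row.get("compound", "")).lower() in ("true", "1", "yes")
    return _rules_from_mappings(rows)


def default_rules() -> list[KeywordRule]:
    """The packaged default keyword -> NS mapping."""
    ref = resources.files("deepsub") / "data" / "default_rules.yaml"
    doc = yaml.safe_load(ref.read_text())
    return _rules_from_mappings(doc["rules"])


def build_dataset(
    source: str | Path | BinaryIO | bytes,
    rules: Iterable[KeywordRule] | None = None,
    drop_fragments: bool = False,
) -> tuple[list[LabeledProtein], CurationReport]:
    """Run the full curation pipeline: parse, filter, label.

    Equals ``assign_label ∘ filter_evidence ∘ parse_uniprot_xml`` with
    unlabeled entries dropped. The report counts every discard by reason,
    so ``n_parsed == n_retained + sum(discards.values())`` always holds.
    """
    rules = _check_rules(rules if rules is not None else default_rules())
    report = CurationReport()
    dataset: list[LabeledProtein] = []
    for entry in parse_uniprot_xml(source):
        report.n_parsed += 1
        retain, reason = filter_evidence(entry)
        if not retain:
            report.discard(reason)  # type: ignore[arg-type]
            continue
        if drop_fragments and entry.is_fragment:
            report.discard(REASON_FRAGMENT)
            continue
        label = assign_label(entry.subunit_text, rules)
        if label is None:
            report.discard(REASON_UNLABELED)
            continue
        matched = _matched_pattern(entry.subunit_text, rules, label)
        dataset.append(
            LabeledProtein(
                accession=entry.accession,
                sequence=entry.sequence,
                ns_label=label,
                matched_rule=matched,
                ec_numbers=list(entry.ec_numbers),
                organism=entry.organism,
            )
        )
        report.n_retained += 1
    return dataset, report


def _matched_pattern(text: str, rules: list[KeywordRule], label: int) -> str:
    norm = _normalise(text)
    for rule in rules:
        if rule.label == label and _word_regex(rule.pattern).search(norm):
            return rule.pattern
    return ""


def write_dataset_tsv(dataset: Iterable[LabeledProtein], path: str | Path) -> None:
    """TSV with columns accession, organism, ns_label, matched_rule,
    ec_numbers (semicolon-joined), sequence."""
    with open(path, "w") as fh:
        fh.write("accession\torganism\tns_label\tmatched_rule\tec_numbers\tsequence\n")
        for rec in dataset:
            fh.write(
                f"{rec.accession}\t{rec.organism}\t{rec.ns_label}\t{rec.matched_rule}\t"
                f"{';'.join(rec.ec_numbers)}\t{rec.sequence}\n"
            )


def read_dataset_tsv(path: str | Path) -> list[LabeledProtein]:
    dataset = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            dataset.append(
                LabeledProtein(
                    accession=row["accession"],
                    sequence=row["sequence"],
                    ns_label=int(row["ns_label"]),
                    matched_rule=row.get("matched_rule", ""),
                    ec_numbers=[e for e in row.get("ec_numbers", "").split(";") if e],
                    organism=row.get("organism", ""),
                )
            )
    return dataset


def write_fasta(dataset: Iterable[LabeledProtein], path: str | Path) -> None:
    """Companion FASTA keyed by accession."""
    with open(path, "w") as fh:
        for rec in dataset:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
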