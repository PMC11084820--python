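"""Curation pipeline: streaming XML parse, evidence filters, keyword labels."""

import random

import pytest
from lxml import etree

from deepsub import curation, fixtures
from deepsub.curation import (
    KeywordRule,
    assign_label,
    build_dataset,
    default_rules,
    filter_evidence,
    parse_uniprot_xml,
)


def dom_parse_entries(xml_bytes: bytes) -> list[dict]:
    """Independent whole-document (DOM) extraction used as the oracle for
    the streaming parser."""
    root = etree.fromstring(xml_bytes)

    def local(elem):
        return etree.QName(elem).localname

    out = []
    for entry in root:
        if local(entry) != "entry":
            continue
        rec = {
            "accession": "", "sequence": "", "organism": "", "protein_name": "",
            "ec_numbers": [], "subunit_text": "", "evidence_codes": [], "is_fragment": False,
        }
        keymap = {}
        for el in entry.iter():
            tag = local(el)
            if tag == "accession" and not rec["accession"]:
                rec["accession"] = el.text.strip()
            elif tag == "fullName" and not rec["protein_name"]:
                rec["protein_name"] = (el.text or "").strip()
            elif tag == "name" and el.get("type") == "scientific":
                rec["organism"] = rec["organism"] or (el.text or "").strip()
            elif tag == "ecNumber":
                rec["ec_numbers"].append(el.text.strip())
            elif tag == "evidence" and el.get("key"):
                keymap[el.get("key")] = el.get("type")
            elif tag == "sequence":
                rec["sequence"] = "".join((el.text or "").split())
                rec["is_fragment"] = el.get("fragment") is not None
        for comment in entry:
            if local(comment) == "comment" and comment.get("type") == "subunit":
                for text in comment:
                    if local(text) == "text":
                        rec["subunit_text"] = (text.text or "").strip()
                        rec["evidence_refs"] = (text.get("evidence") or "").split()
        rec["evidence_codes"] = [keymap[k] for k in rec.pop("evidence_refs", []) if k in keymap]
        out.append(rec)
    return out


class TestParseUniProtXML:
    def test_missing_subunit_comment_yields_empty_text(self):
        xml = fixtures.make_toy_xml(
            [
                fixtures.EntryDescriptor("P1", "MKV", subunit_text="Monomer."),
                fixtures.EntryDescriptor("P2", "MKVA"),
            ]
        )
        entries = list(parse_uniprot_xml(xml.encode()))
        assert len(entries) == 2
        assert entries[0].subunit_text == "Monomer."
        assert entries[1].subunit_text == ""

    def test_similarity_evidence_code_resolved_from_keys(self):
        xml = fixtures.make_toy_xml(
            [fixtures.EntryDescriptor("P1", "MKV", subunit_text="Homodimer.",
                                      evidence_codes=["ECO:0000250"])]
        )
        (entry,) = parse_uniprot_xml(xml.encode())
        assert "ECO:0000250" in entry.evidence_codes

    @pytest.mark.parametrize("namespaced", [True, False])
    def test_streaming_parse_equals_dom_parse(self, namespaced):
        descriptors = fixtures.random_descriptors(1000, seed=11)
        xml = fixtures.make_toy_xml(descriptors, namespaced=namespaced).encode()
        streamed = list(parse_uniprot_xml(xml))
        oracle = dom_parse_entries(xml)
        assert len(streamed) == len(oracle) == 1000
        for got, want in zip(streamed, oracle):
            for field in ("accession", "sequence", "organism", "protein_name",
                          "ec_numbers", "subunit_text", "evidence_codes", "is_fragment"):
                assert getattr(got, field) == want[field], (got.accession, field)

    def test_malformed_xml_raises_with_position(self):
        with pytest.raises(etree.XMLSyntaxError):
            list(parse_uniprot_xml(b"<uniprot><entry><accession>P1</accession>"))

    def test_entry_without_sequence_skipped_with_warning(self, caplog):
        xml = (
            b"<uniprot><entry><accession>P1</accession></entry>"
            b"<entry><accession>P2</accession><sequence>MKV</sequence></entry></uniprot>"
        )
        with caplog.at_level("WARNING", logger="deepsub.curation"):
            entries = list(parse_uniprot_xml(xml))
        assert [e.accession for e in entries] == ["P2"]
        assert any("skipping entry" in rec.message for rec in caplog.records)


class TestFilterEvidence:
    @pytest.mark.parametrize(
        "text,codes,retain,reason",
        [
            ("", [], False, "no-subunit-description"),
            ("Homodimer (By similarity).", [], False, "qualifier"),
            ("Probable monomer.", [], False, "qualifier"),
            ("Potential homotetramer.", [], False, "qualifier"),
            ("Homodimer.", ["ECO:0000269"], True, None),
            ("Homodimer.", ["ECO:0000250"], False, "similarity-evidence"),
            # reason order: empty text wins over evidence, evidence over qualifier
            ("", ["ECO:0000250"], False, "no-subunit-description"),
            ("Homodimer (By similarity).", ["ECO:0000250"], False, "similarity-evidence"),
        ],
    )
    def test_retention_and_reason(self, text, codes, retain, reason):
        entry = curation.UniProtEntry("P1", "MKV", subunit_text=text, evidence_codes=codes)
        assert filter_evidence(entry) == (retain, reason)


class TestAssignLabel:
    @pytest.mark.parametrize(
        "text,label",
        [
            ("Homooctamer of 4 homodimers; disulfide-linked", 8),
            ("Monomer.", 1),
            ("Homodimer; can also form homotetramers.", None),
            ("Homodimer.", 2),
            ("HOMOTETRAMER.", 4),  # case-insensitive
            ("Forms homohexamers.", 6),  # plural tolerated
            ("Homo-dodecamer.", 12),  # hyphenated spelling folded
            ("Homodecamer.", 10),
            ("Binds DNA.", None),  # no keyword
            ("Monomer and homodimer in equilibrium.", None),  # two base keywords
            ("Homotetramer of two homodimers.", 4),  # compound decides
        ],
    )
    def test_keyword_mapping(self, text, label):
        assert assign_label(text, default_rules()) == label

    def test_base_keyword_does_not_match_inside_longer_word(self):
        # "homodecamer" must not fire inside "homododecamer"
        assert assign_label("Homododecamer.", default_rules()) == 12

    @pytest.mark.parametrize("seed", range(5))
    def test_rule_order_independence(self, seed):
        texts = [
            "Monomer.", "Homodimer.", "Homooctamer of 4 homodimers.",
            "Homodimer; can also form homotetramers.", "Homopentamer.",
            "Homotetramer of two homodimers.", "Nothing relevant.",
        ]
        rules = default_rules()
        shuffled = rules[:]
        random.Random(seed).shuffle(shuffled)
        for text in texts:
            assert assign_label(text, shuffled) == assign_label(text, rules)

    def test_duplicate_priorities_rejected(self):
        rules = [
            KeywordRule("monomer", 1, priority=1),
            KeywordRule("homodimer", 2, priority=1),
        ]
        with pytest.raises(ValueError, match="duplicate priorities"):
            assign_label("Monomer.", rules)


class TestBuildDataset:
    def test_six_entry_fixture_hand_enumeration(self, six_entry_descriptors):
        xml = fixtures.make_toy_xml(six_entry_descriptors)
        dataset, report = build_dataset(xml.encode())
        assert {(r.accession, r.ns_label) for r in dataset} == {("P00005", 8), ("P00006", 1)}
        assert report.discards == {
            "no-subunit-description": 1,
            "similarity-evidence": 1,
            "qualifier": 1,
            "unlabeled": 1,
        }
        assert report.n_parsed == 6 and report.n_retained == 2

    def test_empty_xml(self):
        xml = fixtures.make_toy_xml([])
        dataset, report = build_dataset(xml.encode())
        assert dataset == [] and report.n_parsed == 0 and report.discards == {}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation(self, seed):
        xml = fixtures.make_toy_xml(fixtures.random_descriptors(200, seed=seed))
        _, report = build_dataset(xml.encode())
        assert report.n_parsed == report.n_retained + report.n_discarded == 200

    def test_drop_fragments_switch(self):
        descriptors = [
            fixtures.EntryDescriptor("P1", "MKV", subunit_text="Monomer.",
                                     evidence_codes=["ECO:0000269"], is_fragment=True),
            fixtures.EntryDescriptor("P2", "MKVA", subunit_text="Monomer.",
                                     evidence_codes=["ECO:0000269"]),
        ]
        xml = fixtures.make_toy_xml(descriptors).encode()
        kept_default, _ = build_dataset(xml)
        assert {r.accession for r in kept_default} == {"P1", "P2"}  # retained by default
        kept, report = build_dataset(xml, drop_fragments=True)
        assert {r.accession for r in kept} == {"P2"}
        assert report.discards == {"fragment": 1}

    def test_chunk_size_independence(self, six_entry_descriptors):
        import io

        xml = fixtures.make_toy_xml(six_entry_descriptors).encode()

        class TrickleIO(io.RawIOBase):
            """Feeds the parser 7 bytes at a time."""

            def __init__(self, data):
                self.data, self.pos = data, 0

            def readable(self):
                return True

            def readinto(self, b):
                chunk = self.data[self.pos : self.pos + min(len(b), 7)]
                b[: len(chunk)] = chunk
                self.pos += len(chunk)
                return len(chunk)

        whole, _ = build_dataset(xml)
        trickled, _ = build_dataset(io.BufferedReader(TrickleIO(xml)))
        assert [(r.accession, r.ns_label) for r in whole] == [
            (r.accession, r.ns_label) for r in trickled
        ]

    def test_tsv_round_trip(self, six_entry_descriptors, tmp_path):
        xml = fixtures.make_toy_xml(six_entry_descriptors)
        dataset, _ = build_dataset(xml.encode())
        path = tmp_path / "dataset.tsv"
        curation.write_dataset_tsv(dataset, path)
        back = curation.read_dataset_tsv(path)
        assert [(r.accession, r.ns_label, r.sequence, r.ec_numbers) for r in back] == [
            (r.accession, r.ns_label, r.sequence, r.ec_numbers) for r in dataset
        ]
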