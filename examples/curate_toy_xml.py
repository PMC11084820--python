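"""Curate a toy UniProt-dialect XML document into an NS-labeled dataset.

Builds six entries in memory — one without a subunit comment, one backed
only by sequence-similarity evidence (ECO:0000250), one hedged with
"By similarity", one ambiguous (two oligomer keywords), two cleanly
annotated — and runs the full curation pipeline over them.
"""

from deepsub import build_dataset
from deepsub.fixtures import EntryDescriptor, make_toy_xml

descriptors = [
    EntryDescriptor("P00001", "MKVAHEILKA"),
    EntryDescriptor("P00002", "MKVCHEILKA", subunit_text="Monomer.",
                    evidence_codes=["ECO:0000250"]),
    EntryDescriptor("P00003", "MKVDHEILKA", subunit_text="Homodimer (By similarity).",
                    evidence_codes=["ECO:0000269"]),
    EntryDescriptor("P00004", "MKVEHEILKA",
                    subunit_text="Homodimer; can also form homotetramers.",
                    evidence_codes=["ECO:0000269"]),
    EntryDescriptor("P00005", "MKVFHEILKA",
                    subunit_text="Homooctamer of 4 homodimers; disulfide-linked.",
                    evidence_codes=["ECO:0000269"], organism="Homo sapiens"),
    EntryDescriptor("P00006", "MKVGHEILKA", subunit_text="Monomer.",
                    evidence_codes=["ECO:0000269"], organism="Escherichia coli"),
]

xml = make_toy_xml(descriptors)
dataset, report = build_dataset(xml.encode())

print(f"parsed {report.n_parsed} entries, retained {report.n_retained}")
print("discards by reason:", dict(sorted(report.discards.items())))
for rec in dataset:
    print(f"  {rec.accession}: NS={rec.ns_label} (matched rule: {rec.matched_rule!r})")
print()
print("The nested description 'Homooctamer of 4 homodimers' labels as 8:")
print("the compound '<mer> of' rule names the outermost assembly, so the")
print("inner 'homodimers' keyword cannot mislabel the octamer.")
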