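# Default keyword -> NS mapping used to label UniProt subunit comments.
#
# Compound rules ("<homo-n-mer> of ...") take precedence over base keywords:
# a description such as "Homooctamer of 4 homodimers" names two oligomer
# terms, but the "of" phrasing identifies the outermost assembly, so the
# compound rule decides the label immediately. Base keywords only label an
# entry when exactly one distinct term occurs in the description; zero or
# two-plus distinct terms leave the entry unlabeled to avoid false positives.
#
# Lower priority numbers are applied first. Priorities must be unique.
rules:
  - {pattern: "homodimer of", label: 2, priority: 1, compound: true}
  - {pattern: "homotrimer of", label: 3, priority: 2, compound: true}
  - {pattern: "homotetramer of", label: 4, priority: 3, compound: true}
  - {pattern: "homopentamer of", label: 5, priority: 4, compound: true}
  - {pattern: "homohexamer of", label: 6, priority: 5, compound: true}
  - {pattern: "homoheptamer of", label: 7, priority: 6, compound: true}
  - {pattern: "homooctamer of", label: 8, priority: 7, compound: true}
  - {pattern: "homodecamer of", label: 10, priority: 8, compound: true}
  - {pattern: "homododecamer of", label: 12, priority: 9, compound: true}
  - {pattern: "monomer", label: 1, priority: 11, compound: false}
  - {pattern: "homodimer", label: 2, priority: 12, compound: false}
  - {pattern: "homotrimer", label: 3, priority: 13, compound: false}
  - {pattern: "homotetramer", label: 4, priority: 14, compound: false}
  - {pattern: "homopentamer", label: 5, priority: 15, compound: false}
  - {pattern: "homohexamer", label: 6, priority: 16, compound: false}
  - {pattern: "homoheptamer", label: 7, priority: 17, compound: false}
  - {pattern: "homooctamer", label: 8, priority: 18, compound: false}
  - {pattern: "homodecamer", label: 10, priority: 19, compound: false}
  - {pattern: "homododecamer", label: 12, priority: 20, compound: false}
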