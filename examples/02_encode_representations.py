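"""Turn raw records into the four fixed-shape model inputs.

Shows the classical encoding arithmetic: a sequence padded to 1,500 residues
yields 1,498 sliding trigrams and a 1,498 x 100 embedding matrix; domain hits
are deduplicated, sorted by regional center point and mapped to a padded
integer sentence; scored links above 400 fill a symmetric PPI matrix.
"""

import numpy as np

from gofuse import encode, simulate
from gofuse.io import DomainHit, ScoredLink

table = simulate.make_protvec_stub(seed=0)

seq = "MKVLHEQPW" * 30  # 270 residues
padded = encode.pad_sequence(seq)                 # length 1,500
tokens = encode.extract_trigrams(padded)          # 1,498 tokens
matrix = encode.embed_trigrams(tokens, table, expected_len=1498)
print(f"padded length {len(padded)} -> {len(tokens)} trigrams -> matrix {matrix.shape}")
print(f"rows beyond the real sequence are zero: {np.abs(matrix[270:]).max() == 0.0}")

hits = [
    DomainHit("P1", "IPR000001", 60, 200),   # center 130
    DomainHit("P1", "IPR000002", 100, 140),  # center 120, contained in the first
    DomainHit("P1", "IPR000003", 210, 250),  # detached, right of both
]
ordered = encode.sort_domains(encode.dedup_domain_hits(hits))
print("domain sentence order:", [h.domain_id for h in ordered])
vocab = encode.build_domain_vocab(hits)
print("sentence indices:", encode.encode_domain_sentence(ordered, vocab, max_len=5))

links = [ScoredLink("P1", "P2", 700), ScoredLink("P2", "P3", 400)]
ppi = encode.build_ppi_matrix(links, ["P1", "P2", "P3"])
print("PPI matrix (score 400 dropped, strictly-greater filter):")
print(ppi)
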