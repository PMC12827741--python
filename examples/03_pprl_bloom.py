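"""Privacy-preserving comparison: Bloom-encoded names, same Dice verdict.

Encodes two name variants under a shared secret and compares the
encoded Dice similarity with the clear-text bigram Dice the filters
approximate — close enough to drive the same linkage decision, without
either side revealing the plaintext.
"""

import pseudolink as pl

config = pl.BloomFilterConfig(hmac_secret=b"shared-site-secret", m=500, k=10)

for a, b in [("SCHNEIDER", "SCHNEIDR"), ("MUELLER", "MUELLER"), ("MEIER", "HUBER")]:
    ga, gb = pl.extract_ngrams(a), pl.extract_ngrams(b)
    fa, fb = pl.bloom_encode(ga, config), pl.bloom_encode(gb, config)
    print(f"{a:10s} vs {b:10s}  clear-text Dice {pl.dice_cleartext(ga, gb):.3f}  "
          f"Bloom Dice {pl.dice_similarity(fa, fb):.3f}")

field = pl.bloom_encode(pl.extract_ngrams("SCHNEIDER"), config)
print(f"\nserialized filter (hex, no plaintext): {field.to_hex()[:48]}...")
print(f"set bits: {field.cardinality} of {field.m}")

# Each bigram sets k positions via keyed double hashing; without the HMAC
# secret the filter cannot be regenerated from a name, and the comparison
# works on the bitsets alone.
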