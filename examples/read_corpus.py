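"""Parse a PubTator-format document and enumerate its relation instances.

Reads an annotated abstract from an inline string, splits it into sentences
using its dependency parses, and shows which chemical-disease mention pairs
become intra- vs inter-sentence instances.
"""

import io

from cidre import build_instances, read_parses, read_pubtator, split_sentences

PUBTATOR = """\
100|t|The oxapril induced severe hemopathy .
100|a|The patient tolerated oxapril well . The chart noted mild arthritis previously .
100\t4\t11\toxapril\tChemical\tD1019
100\t27\t36\themopathy\tDisease\tD2020
100\t61\t68\toxapril\tChemical\tD1019
100\t97\t106\tarthritis\tDisease\tD2021
100\tCID\tD1019\tD2020
"""

PARSES = """\
#100\t0
1\tThe\tthe\tDT\t2\tdet\t0\t3
2\toxapril\toxapril\tNN\t3\tnsubj\t4\t11
3\tinduced\tinduce\tVBD\t0\troot\t12\t19
4\tsevere\tsevere\tJJ\t5\tamod\t20\t26
5\themopathy\themopathy\tNN\t3\tdobj\t27\t36
6\t.\t.\t.\t3\tpunct\t37\t38

#100\t1
1\tThe\tthe\tDT\t2\tdet\t39\t42
2\tpatient\tpatient\tNN\t3\tnsubj\t43\t50
3\ttolerated\ttolerate\tVBD\t0\troot\t51\t60
4\toxapril\toxapril\tNN\t3\tdobj\t61\t68
5\twell\twell\tRB\t3\tadvmod\t69\t73
6\t.\t.\t.\t3\tpunct\t74\t75

#100\t2
1\tThe\tthe\tDT\t2\tdet\t76\t79
2\tchart\tchart\tNN\t3\tnsubj\t80\t85
3\tnoted\tnote\tVBD\t0\troot\t86\t91
4\tmild\tmild\tJJ\t5\tamod\t92\t96
5\tarthritis\tarthritis\tNN\t3\tdobj\t97\t106
6\tpreviously\tpreviously\tRB\t3\tadvmod\t107\t117
7\t.\t.\t.\t3\tpunct\t118\t119
"""

docs = read_pubtator(io.StringIO(PUBTATOR))
trees = read_parses(io.StringIO(PARSES))
doc = docs[0]
print(f"document {doc.doc_id}: {len(doc.mentions)} mentions, "
      f"gold relations {sorted(doc.gold_relations)}")

views = split_sentences(doc, trees)
for v in views:
    forms = [m.text for m in v.mentions]
    print(f"  sentence {v.index}: mentions {forms}")

intra, inter = build_instances(doc, views)
print(f"\n{len(intra)} intra-sentence instance(s):")
for inst in intra:
    print(f"  {inst.pair} in sentence {inst.sentence_index}")
print(f"{len(inter)} inter-sentence instance(s):")
for inst in inter:
    print(f"  {inst.pair} across sentences {inst.sentence_index_pair}")
print("\nPairs co-occurring in a sentence stay intra-level; concept pairs")
print("that never share a sentence are paired across sentences instead.")
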