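"""Build a small synthetic carrot-defect corpus and inspect the protocol.

Renders 10 images per defect class at 96 px, splits them 6:4 into the clean
teacher partition T and the student partition S, splits each 3:1:1 into
train/val/test, and degrades 2+2 student images per class (2x / 4x resolution
reduction plus motion blur).  Prints the resulting counts; they follow the
acquisition protocol exactly.
"""

from collections import Counter

from distilharvest import CorpusSpec, build_corpus

spec = CorpusSpec(per_class_count=10, image_side=96, degrade_per_class=(2, 2),
                  seed=7)
corpus, plan = build_corpus(spec)

print(f"total images: {len(corpus)}")                       # 50
datasets = Counter(v[0] for v in plan.assignments.values())
print(f"teacher set T: {datasets['T']}, student set S: {datasets['S']}")  # 30/20
tags = Counter(im.degradation_tag for im in corpus)
print(f"degradation tags: {dict(tags)}")                    # 10 x2, 10 x4
subsets = Counter(v for v in plan.assignments.values())
for key in sorted(subsets):
    print(f"  {key}: {subsets[key]} images")

im = corpus[0]
cid, cx, cy, w, h = im.objects[0]
print(f"first image {im.source_id}: class {cid}, box centred at "
      f"({cx:.2f}, {cy:.2f}), {w:.2f} x {h:.2f} (normalized)")
# Uncomment to write PNGs + YOLO txt labels + a TSV manifest:
# from distilharvest.synthcarrot import write_corpus
# write_corpus(corpus, plan, "corpus_out")
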