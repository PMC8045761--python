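"""Recompute published worked-example fold changes from their printed means.

Builds a noise-free one-gene signal matrix per example (two duplicated
replicates per cell, as in the study design), runs the contrast summary, and
prints the signed fold change. A value of -1.70 means the gene's signal drops
1.70-fold under cold; positive values are plain cold/control ratios.
"""

import numpy as np

from polysel import Condition, DesignCell, Fraction, Genotype, SampleMeta, SignalMatrix
from polysel import summarize_contrast

EXAMPLES = [
    ("AT1G05010", "WT", "TOTAL", 263.96, 155.29),
    ("AT5G59820", "WT", "TOTAL", 11.83, 29.44),
    ("AT1G11680", "WT", "POLY", 8.10, 4.57),
    ("AT3G61190", "WT", "POLY", 2.54, 8.35),
    ("AT2G35500", "MUT", "TOTAL", 54.41, 46.25),
]

for gene, genotype, fraction, ck, cold in EXAMPLES:
    samples, cols = [], []
    for condition, mean in ((Condition.CK, ck), (Condition.COLD, cold)):
        for r in (1, 2):
            samples.append(SampleMeta(f"{condition.value}{r}", Genotype(genotype),
                                      condition, Fraction(fraction), r))
            cols.append(mean)
    matrix = SignalMatrix([gene], samples, np.array([cols]))
    ref = DesignCell(Genotype(genotype), Condition.CK, Fraction(fraction))
    alt = DesignCell(Genotype(genotype), Condition.COLD, Fraction(fraction))
    (res,) = summarize_contrast(matrix, ref, alt)
    print(f"{gene} ({genotype}, {fraction.lower()}): "
          f"{ck:>7.2f} -> {cold:>7.2f}  signed fold {res.signed_fold:+.2f}")
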