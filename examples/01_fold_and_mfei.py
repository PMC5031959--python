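"""Fold a candidate precursor and decide whether it could host a novel miRNA.

Builds a textbook stem-loop, folds it with the weighted Nussinov DP, and
applies the two novel-miRNA hairpin gates: single stem-loop with the mature
inside one arm, and MFEI >= 0.80.
"""

from srnapipe import fold_internal, make_hairpin_record, validate_hairpin

ARM = "GCAUGGACUGAAGCUAGCUAGCA"            # 23-nt arm hosting the mature
COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
precursor = ARM + "AACAA" + "".join(COMP[c] for c in reversed(ARM))

record = make_hairpin_record(fold_internal(precursor))
ok, reasons = validate_hairpin(record, (1, len(ARM)), mfei_min=0.80)

print(f"sequence  ({len(precursor)} nt): {precursor}")
print(f"structure          : {record.fold.structure}")
print(f"MFE                : {record.fold.mfe:.1f} kcal/mol "
      f"({record.fold.n_pairs} pairs)")
print(f"GC%                : {record.gc_percent:.1f}")
print(f"MFEI               : {record.mfei:.2f}  (novel gate: >= 0.80)")
print(f"single stem-loop   : {record.is_stem_loop}")
print(f"5p arm / 3p arm    : {record.arm5} / {record.arm3}")
print(f"valid novel host   : {ok}  {('(' + ','.join(reasons) + ')') if reasons else ''}")
# A high MFEI means the fold is unusually stable for the sequence's GC
# content -- the hallmark of a genuine pre-miRNA versus a random fragment.
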