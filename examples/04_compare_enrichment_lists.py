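"""Compare two enrichment result lists with the log-ratio statistic.

Two clusterings of the same genes each produce a table of term -> p-value
(for example GO enrichment of the resulting clusters).  On the shared
terms, count how often each side has the strictly smaller p-value; the
statistic ln(#(r1 < r2) / #(r2 < r1)) is positive when the first list is
the stronger one, and swapping the lists only flips its sign.
"""

from corrdist import PValueList, compare_pvalue_lists

r1 = PValueList({
    "GO:0006955": 0.001, "GO:0007049": 0.020, "GO:0008152": 0.004,
    "GO:0006412": 0.047, "GO:0016070": 0.300, "GO:0009058": 0.90,
})
r2 = PValueList({
    "GO:0006955": 0.005, "GO:0007049": 0.015, "GO:0008152": 0.030,
    "GO:0006412": 0.049, "GO:0016070": 0.100, "GO:0042254": 0.02,
})

res = compare_pvalue_lists(r1, r2)
print(f"shared terms: {res.n_shared} "
      f"(excluded: {res.n_only_first} only in r1, {res.n_only_second} only in r2)")
print(f"#(r1 < r2) = {res.n_first_smaller}, #(r2 < r1) = {res.n_second_smaller}")
print(f"statistic ln(ratio) = {res.statistic:+.3f}")
rev = compare_pvalue_lists(r2, r1)
print(f"swapped arguments   = {rev.statistic:+.3f}  (sign flips, magnitude equal)")
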