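"""RPKM and cross-sample fold change, checked against the published
germ-cell piRNA expression table bundled with the package."""

import pirnapipe as pp
from pirnapipe import reference

# a single tag: 8 reads of a 26-nt tag in a 10,000-read library
value = pp.rpkm(count=8, length=26, total_clean_reads=10_000)
print(f"RPKM(8 reads, 26 nt, 10k library) = {value:,.1f}")

# fold change of the top published repeat-derived piRNA tag
pirnas = reference.top_pirnas().set_index("tag_id")
row = pirnas.loc["ISG_3439104"]
rpkms = dict(zip(reference.SAMPLES,
                 [float(row.rpkm_pgc), float(row.rpkm_stagex),
                  float(row.rpkm_gsc), float(row.rpkm_cef)]))
fc = pp.fold_change(rpkms, "PGCs")
print(f"ISG_3439104 RPKMs {rpkms} -> fold change {fc:.2f} "
      f"(published: {row.fold_change_reported})")

# the zero-reference case exercises the pseudocount floor (0.01)
row = pirnas.loc["ISG_2087909"]
fc = pp.fold_change(dict(zip(reference.SAMPLES,
                             [row.rpkm_pgc, 0.0, 0.0, 0.0])), "PGCs")
print(f"ISG_2087909 (absent elsewhere) -> fold change {fc:.2f} "
      f"(published: {row.fold_change_reported})")

# A tag is called upregulated in the focal sample when this ratio >= 2.
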