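"""Digest two isoforms of one gene and classify peptide uniqueness.

The variant isoform carries a private C-terminal segment; its peptides are
isoform-unique (evidence for that specific variant), while shared backbone
peptides are only gene-unique.
"""

from matricount import DigestParams, IsoformRecord, build_peptide_index, digest

backbone = "MAAAGPKGDRGPPGSSKGEELTNKVVVDDKPPPGSSK"
tail = "WWFFYYHHMMNNQQCCDDEE"
isoforms = [
    IsoformRecord("col_c", "colA", "canonical", backbone),
    IsoformRecord("col_v1", "colA", "ALT-20", backbone + tail),
]

params = DigestParams(max_missed_cleavages=1, min_length=4, max_length=50)
print("tryptic peptides of the canonical isoform (0-1 missed cleavages):")
for occ in digest(backbone, params):
    print(f"  {occ.peptide:<22} {occ.start:>3}-{occ.end:<3} mc={occ.missed_cleavages}")

index = build_peptide_index(isoforms, params)
print("\npeptide uniqueness classes (isoform_unique peptides pin the variant):")
for pep in sorted(index.occurrences):
    occs = ",".join(sorted({o.accession for o in index.occurrences[pep]}))
    print(f"  {pep:<22} {index.classes[pep]:<15} [{occs}]")
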