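# Canonical VHL coding-exon map in cDNA coordinates.
# The exon1/exon2 and exon2/exon3 junctions are fixed by the canonical
# splice acceptors at c.341-1 and c.464-1; the CDS ends at c.642
# (213 codons + stop).  The cryptic exon E1' has no standardized
# boundaries; the window below is a declared approximation given as
# intron-1 offsets from c.340 and is echoed in output metadata.
transcript_id: NM_000551.4
cds_exon_bounds:
  - [1, 340]
  - [341, 463]
  - [464, 642]
e1prime_window: [400, 800]
utr_allowance: 200
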