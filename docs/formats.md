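# File format subsets

All internal coordinates are 0-based half-open bp. The writers below alone
emit the optical-mapping ecosystem's 1-based positions; the readers convert
back. Lines starting with `#` are headers/comments; unknown header lines are
ignored. Columns are tab-separated.

## BNX subset (single-molecule maps)

```
# free-form header lines
0 <molecule_id> <length_bp>
1 <pos_1> <pos_2> ... <pos_k>     # 1-based bp, label channel 1
```

A `0` line without a following `1` line is a molecule with an empty label
channel.

## CMAP subset (reference / contig maps)

One row per label (channel 1), plus a channel-0 terminator row per map:

```
#h CMapId ContigLength NumSites SiteID LabelChannel Position
```

## XMAP subset (alignments)

```
#h XmapEntryID QryContigID RefContigID RefStartPos RefEndPos Orientation Score Confidence Alignment
```

`Alignment` is the pair string `(ref_site,qry_site)(...)`, 1-based site
indices.

## SMAP-like SV calls

```
#h chrom start end type size_delta zygosity support score module chrom2 sample_id
```

`start` is 1-based on disk; `chrom2` holds the partner chromosome of
inter-chromosomal break ends, `.` otherwise.

## BED and TSV

BED output is 0-based half-open. Cohort metadata is a TSV with columns
`sample_id`, `population`, `super_population` (AFR/AMR/EAS/EUR/SAS), `sex`.
Configuration files are INI-style; every threshold in `AlignParams`,
`NoiseModel`, and the callers can be set there (see `omvar.io.load_config`).
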