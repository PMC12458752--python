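# crctnm

Rule-based extraction of **explicit TNM staging** and **primary
colorectal-cancer (CRC) status** from free-text imaging and histopathology
reports, plus a synthetic report generator and an evaluation harness
(micro-averaged PPV/NPV/sensitivity/specificity with 95% Wilson intervals).

## What it does

- **TNM extraction** (`crctnm.tnm`): finds staging phrases anywhere in a
  report, covering common documentation variants — multiple values per
  category (`T1/2/3`), zero mis-typed as O (`NO`), lower case, missing or
  extra gaps (`T1N0M0`, `T 1`), prefixes (`pT1`, `ypT1`, `ymrT1`),
  bracketed comments (`T1a (solitary tumour) N0`), variable order, and
  cue-anchored singletons (`Staged as T2`). Look-alikes such as MRI
  sequence names (`T1-weighted`) and vertebral levels (`T1-T12`, `L1`) are
  rejected by context guards. Per report, the maximum value of each of the
  11 categories (Tpre, T, N, M, V, R, L, Pn, G, SM, H) is reported under a
  clinical severity ordering; `X` is reported only when it is the sole
  observation.
- **CRC detection** (`crctnm.crc`): matches tumour keywords, links them to
  colorectal site terms in the same sentence, and excludes mentions under
  negated / historical / general / non-definite / metastasis / recurrence /
  treatment-response modifier scopes (ConText-style trigger rules,
  `crctnm.context`). Included and excluded phrases are output with
  surrounding context for review.
- **Synthetic corpus** (`crctnm.synth`): seeded generator of sectioned
  pathology and imaging reports with exhaustive gold annotations, an
  enumerator of the full staging grammar (1178 phrase/parse pairs), and a
  distractor bank of strings that must never parse.
- **Evaluation** (`crctnm.metrics`): per-category confusion counts,
  micro-averaged PPV/sensitivity, NPV/specificity versus the no-value
  class, 95% Wilson score intervals, and two scoring scenarios (`strict`
  vs `explicit_only` handling of implicit and historical staging).

All rule parameters (cue lists, windows, separators, prefix whitelist,
guard patterns) are configurable via YAML; the trigger and keyword
lexicons are plain-text files shipped under `src/crctnm/lexicons/` and can
be replaced wholesale. Note: the extractor targets staging written in
letters and numbers only — it does not infer implicit staging.

## CLI

```bash
# generate a synthetic corpus with gold annotations
crctnm simulate --n 1000 --seed 42 --output synth.jsonl --gold gold.jsonl

# extract TNM maxima (optionally phrase-level output, parallel workers)
crctnm extract-tnm --input synth.jsonl --format jsonl --output tnm.csv \
    --phrases phrases.csv --workers 4

# detect primary CRC
crctnm detect-crc --input synth.jsonl --format jsonl --output crc.csv

# score predictions against gold
crctnm evaluate --pred tnm.csv --gold gold.jsonl --task tnm \
    --scenario strict --output metrics.csv
crctnm evaluate --pred crc.csv --gold gold.jsonl --task crc --output crc_metrics.csv
```

Input corpora are CSV or JSON-lines with columns `report_id`,
`report_type` (`pathology`|`imaging`), `text` and optional `date`
(remappable via `column_map` in the library API). Exit codes: 0 success,
1 validation error, 2 usage error.

A YAML config can override any rule parameter, e.g.:

```yaml
tnm:
  cues: ["staged as", "stage", "tnm"]
  multi_value_separators: ["/"]
lexicons:
  triggers: my_triggers.tsv
```

## Known limitations

- Supplementary gene-testing reports that mention no explicit CRC keyword
  are not detected (by design — mirrors the known gap of the rule set).
- Grade (G) is extracted only when written with the letter G; prose grades
  ("moderately differentiated") are out of scope.
- No spell-checking beyond the O→0 substitution; no TNM edition detection.
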