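# mcckit

A toolkit for standardized measurement of chronic conditions and
multimorbidity (MCC) across heterogeneous health data systems. It packages:

- **registry** — a machine-readable encoding of a 20-condition chronic-condition
  classification scheme, with per-condition code mappings for five national
  data-system dialects (NHIS self-report, NAMCS chart checkboxes, MEPS and
  NIS CCS categories, CMS ICD-9-CM claims codes), sub-condition aliases, an
  availability matrix (measured / related-proxy / unavailable), and metadata
  mirrors of the published definition and scheme-comparison tables.
- **code_systems** — parsing, normalization, and membership semantics for
  ICD-9-CM and CCS vocabularies, including the comma-list/range cell syntax
  used by the printed mapping table.
- **coder** — applies the scheme to claims or survey records under a chosen
  dialect, producing one condition profile (20 boolean flags + count +
  evidence) per person, visit, or hospitalization.
- **indicators** — per-condition prevalence, MCC prevalence (default
  threshold: 2 or more concurrent conditions), top-coded condition-count
  distribution, dyad co-occurrence, cross-system coverage report, and
  dialect-to-dialect discordance tables.
- **synthetic_data** — a Gaussian-copula population generator with
  configurable prevalences and pairwise associations, claims emission with
  non-scheme decoy codes, and survey emission with
  sensitivity/specificity misclassification, so the full pipeline is
  testable without restricted data.

## CLI

```sh
# 20 x 5 availability/coverage table with per-system totals
mcckit coverage

# validate the packaged registry and export the audit code list
mcckit validate-registry --export-codes codes.csv

# simulate a population and emit claims for the CMS dialect
mcckit simulate --config config.yaml --dialect CMS \
    --truth-out truth.csv --records-out claims.csv

# code claims into per-unit condition profiles
mcckit code claims.csv --dialect CMS --out profiles.csv

# population indicators (MCC threshold defaults to 2)
mcckit indicators profiles.csv --out report.json
```

A minimal simulation config:

```yaml
n_units: 1000
prevalence:
  hypertension: 0.3
  diabetes: 0.2
  asthma: 0.1
seed: 7
```

Claims CSV is long format (`unit_id,record_id,code,code_system`, one code
per row); survey CSV is `unit_id,item,response` with responses
yes/no/missing. Outputs embed the scheme version, registry checksum, and
config echo as `#` comment headers; existing files are not overwritten
without `--force`.

## Notes on fidelity

The packaged registry stores every mapping-table cell verbatim and parses
it at load time; known transcription artifacts (a stray `2` token in one
ICD-9-CM list, a CCS category shared by two conditions, 5-digit ICD-style
values in a CCS column) are preserved and surfaced as validation warnings
rather than silently corrected. Availability states follow the published
narrative counts where the transcribed table disagrees; both provenances
are retained per cell.
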