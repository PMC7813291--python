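# Study database schema

A database is a directory of six CSV tables (RFC 4180, UTF-8, snake_case
headers). Times are fractional months relative to the strategy start
(start = 0; negative = baseline period). Missing values are empty cells and
map to explicit missing states — never silently to "no". Row order is
irrelevant on load; `save_database` writes deterministic column order and
row sort so output files are reproducible byte-for-byte.

## studies.csv

| column | type | notes |
| --- | --- | --- |
| study_id | string | unique |
| design | enum | `randomised`, `non_randomised`, `its`, `its_controlled` |
| cadre | enum | `professional`, `lay` (never missing) |
| country_income | enum | `low`, `middle`, `unknown` |
| strategy_start_month | real | finite; 0 by convention |
| publication_year | int | optional |
| is_equivalency | 0/1 | gold-standard comparison study |
| rob_domains | encoded | `name=status\|name=status`; status ∈ `done`, `not_done`, `unclear`, `not_applicable` |

## arms.csv

`arm_id` (unique), `study_id` (FK), `is_control` (0/1; control arms carry no
components beyond `placebo`), `is_gold_standard` (0/1; reference arm of
equivalency comparisons).

## components.csv

`arm_id` (FK), `component_code`. Codes are collapsed at load time to the
16-category vocabulary (five mutually exclusive training categories:
`group_inservice`, `group_preservice`, `self_study`, `eov`, `peer_to_peer`;
eleven other categories, e.g. `supervision`, `group_problem_solving`,
`printed_materials_standalone`, `ict`; plus `placebo`) via the packaged
mapping `src/hcpmeta/data/component_map.csv`. Unknown codes are rejected;
pass a custom mapping to `load_database` to adapt a differently-coded
export.

## attributes.csv

One row per training arm (required exactly when a training component is
present): `duration_days` (>0 or missing), the five method flags
(`lecture`, `interactive_discussion`, `clinical_practice`, `role_play`,
`other_method`: yes/no/missing), `printed_materials`, `computers`,
`professional_trainers`, `content_expert_trainers`, `multiple_sessions`
(yes/no/missing), `group_size` (int or missing), `topic_complexity`
(`single`/`multiple`/missing), `onsite`
(`some_or_all_onsite`/`all_offsite`/missing).

## outcomes.csv

Long format, one row per measurement: `outcome_id`, `study_id`, `scale`
(`percentage` in [0,100], or `continuous`), `direction`
(`increase_improves`/`decrease_improves`), `arm_id`, `time_month`, `value`,
`n` (optional denominator). Scale and direction must be constant within an
`outcome_id`. Non-ITS designs need at least one follow-up (time ≥ 0) per
measured arm; ITS arms need ≥ 3 pre and ≥ 3 post points to be fit.

## costs.csv

`arm_id` (FK), `total_cost_usd` (≥0), `n_hcps_trained` (>0),
`duration_days` (>0). Cost per HCP per day of training is derived, never
stored.

Validation (`hcpmeta validate <dir>` or `load_database`) checks every
referential-integrity and range rule above and reports each violation as
`table[row]: rule`.
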