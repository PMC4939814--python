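"""How much poverty do out-of-pocket health payments create?

Poverty is measured twice on the same survey: on expenditure as observed
("gross") and after subtracting each household's OOP health payments
("net").  People who are non-poor gross but poor net were pushed below the
line by paying for health care.
"""

from finprot import (
    POVERTY_LINE_PRESETS,
    GeneratorConfig,
    generate_survey,
    impoverished_population,
    impoverishment_effect,
)
from finprot.report import render_table

ds = generate_survey(GeneratorConfig(seed=42))
line = POVERTY_LINE_PRESETS["mongolia_national_2012"]  # 118,668 MNT/person/month

eff = impoverishment_effect(ds, line)
print(render_table(eff, "text"))
print()
dh = eff.absolute_change["head_count"]
print(
    f"Gross head count {eff.gross.head_count:.2%}, net {eff.net.head_count:.2%}: "
    f"OOP payments push {dh:.2%} of people below the line "
    f"({eff.relative_change['head_count']:.1%} relative rise)."
)
# Scaling the head-count change by an external population figure turns the
# rate into a number of people (here: ~2.8 million, Mongolia circa 2012).
print(f"Projected onto 2.8 million people: {impoverished_population(dh, 2_800_000):,} "
      "people impoverished by health payments.")
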