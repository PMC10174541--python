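"""Load the packaged sterilization tables and inspect the design.

Prints the treatment count, the observed extremes of both responses, and
one example row.  The extremes define the utopia point that the
optimizer later aims for.
"""

from sterilopt import DisinfectantKind, load_treatment_tables, observation_table_from_records

records = load_treatment_tables()
table = observation_table_from_records(records)

print(f"{len(records)} printed treatments across {len(DisinfectantKind)} disinfectant tables")
best_germ = max(records, key=lambda r: r.germination_mean)
low_cont = min((r for r in records if r.contamination_mean > 0), key=lambda r: r.contamination_mean)
print(
    f"highest germination: {best_germ.germination_mean}% "
    f"({best_germ.source_table.value} {best_germ.concentration}{best_germ.source_table.unit} "
    f"x {best_germ.immersion_time:g} min)"
)
print(
    f"lowest nonzero contamination: {low_cont.contamination_mean}% "
    f"({low_cont.source_table.value} {low_cont.concentration}{low_cont.source_table.unit} "
    f"x {low_cont.immersion_time:g} min)"
)
print(f"untreated controls: {records[0].contamination_mean}% contamination, "
      f"{records[0].germination_mean}% germination")
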