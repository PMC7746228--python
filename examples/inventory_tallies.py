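"""Load the packaged candidate-GRL inventory and print its tallies.

The inventory lists the 17 candidate GRL proteins recognised across
unicellular eukaryotes (two chytrid fungi, three protist species, two
green algae), with species, kingdom, and accession metadata.
"""

from grlscreen import io

records = io.load_table1()
summary = io.table1_summary(records)

print(f"candidates: {summary['n_candidates']}")
print(f"fungal species represented: {summary['n_fungal_species']}")
for kingdom, count in sorted(summary["by_kingdom"].items()):
    print(f"  {kingdom:10s} {count}")
for species, count in sorted(summary["by_species"].items()):
    print(f"  {species:40s} {count}")

# The counts are the inventory's shape: 17 candidates total, of which
# 6 come from Thecamonas trahens and 6 from Vitrella brassicaformis.
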