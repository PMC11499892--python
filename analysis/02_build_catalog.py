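"""Build the neomer catalog from the simulated recurrent-SNV list:
enumerate 16-mers spanning each alternate allele, keep those absent from
the reference on both strands, drop any attributable to a population
variant."""

from common import COHORT, RUN

from neomer_mrd.catalog import build_catalog, write_catalog
from neomer_mrd.io import read_fasta, read_variants


def main() -> None:
    reference = read_fasta(COHORT / "reference.fa")
    rec = read_variants(COHORT / "recurrent_snvs.tsv")
    pop = read_variants(COHORT / "population_variants.tsv")
    catalog = build_catalog(rec, pop, reference, k=16)
    write_catalog(catalog, RUN / "catalog.tsv")
    p = catalog.provenance
    print(f"catalog written to {RUN / 'catalog.tsv'}")
    print(f"  {p['recurrent_snvs']} recurrent SNVs -> {p['candidates']} candidate "
          f"16-mers -> {p['reference_absent']} reference-absent -> "
          f"{p['final']} neomers after population filtering")


if __name__ == "__main__":
    main()
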