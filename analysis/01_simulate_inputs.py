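"""Generate the synthetic study inputs for the downstream analyses.

Writes, under results/inputs/: a scale-free interactome edge list with a
planted near-module disease set plus uniform control sets (GMT), a
three-experiment sense/antisense/beads pulldown peptide table, a four-donor
paired control/LPS expression matrix with 11 planted up-regulated
transcripts, and the annotation fixture (BED + GFF3) covering the four
positional lncRNA classes.  Truth labels accompany every dataset.
"""

from pathlib import Path

from lncprox import synth
from lncprox.interactome import write_edge_list

SEED = 17
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    g = synth.gen_interactome(2000, seed=SEED)
    write_edge_list(g, OUT / "edges.tsv")
    cand = synth.pick_candidate(g)
    with open(OUT / "diseases.gmt", "w") as fh:
        near, truth = synth.plant_disease_gene_set(
            g, cand, size=20, closeness=2.0, seed=SEED, name="planted_near")
        truth.to_json(OUT / "disease_truth.json")
        fh.write("planted_near\tsynthetic\t" + "\t".join(sorted(near.members)) + "\n")
        for i in range(3):
            ctrl, _ = synth.plant_disease_gene_set(
                g, cand, size=20, closeness=0.0, seed=SEED + 1 + i,
                name=f"uniform_control_{i}")
            fh.write(f"uniform_control_{i}\tsynthetic\t"
                     + "\t".join(sorted(ctrl.members)) + "\n")
    (OUT / "candidate.txt").write_text(cand + "\n")
    print(f"interactome: {len(g)} nodes, candidate {cand} "
          f"(degree {g.degree(cand)})")

    peptides, truth = synth.gen_pulldown_dataset(seed=SEED)
    peptides.to_csv(OUT / "peptides.csv", index=False)
    truth.to_json(OUT / "pulldown_truth.json")
    print(f"pulldown: {peptides.shape[0]} peptide rows, "
          f"planted {sorted(truth.planted['interactors'])}")

    matrix, truth = synth.gen_expression_dataset(n_planted=11, seed=SEED)
    matrix.values.to_csv(OUT / "expr.tsv", sep="\t")
    matrix.design.to_csv(OUT / "design.tsv", sep="\t", index=False)
    truth.to_json(OUT / "screen_truth.json")
    print(f"screen: {matrix.values.shape[0]} transcripts x "
          f"{matrix.values.shape[1]} samples, 11 planted")

    lncs, genes, truth = synth.gen_annotation_fixture(seed=SEED)
    synth.write_annotation_fixture(lncs, genes, OUT / "lncs.bed",
                                   OUT / "genes.gff3")
    truth.to_json(OUT / "annotation_truth.json")
    print(f"annotation: {len(lncs)} lncRNAs over {len(genes)} coding genes")


if __name__ == "__main__":
    main()
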