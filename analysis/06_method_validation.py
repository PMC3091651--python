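#!/usr/bin/env python
"""Method validation on fresh synthetic replicates.

Two checks on the full simulate-and-recover loop: (a) with the default
injected gradient, the pipeline recovers a gene-level expression-distance
Spearman rho near the generative target across independent replicates;
(b) with every distance coefficient zeroed (stationary condition), the
correlation rejects at ~5% — the statistical layer does not manufacture
gradients.
"""

from pathlib import Path

from repliorg.synthetic_data import paper_scale_params, recovery_experiment

SEED = 1


def main() -> None:
    res = recovery_experiment(paper_scale_params(seed=SEED), n_seeds=20)
    print(
        f"gradient recovery over {len(res)} replicates: "
        f"rho = {res['rho'].mean():.3f} +- {res['rho'].std():.3f} "
        f"(max P = {res['p'].max():.2g})"
    )

    null = paper_scale_params(
        seed=SEED, beta1=0.0, core_dist_coef=0.0, transposon_dist_coef=0.0,
        gap_dist_coef=0.0, condition="stationary",
    )
    nres = recovery_experiment(null, n_seeds=100)
    rate = (nres["p"] < 0.05).mean()
    print(
        f"null calibration over {len(nres)} replicates: mean rho = "
        f"{nres['rho'].mean():+.3f}, rejection rate at alpha=0.05: {rate:.3f}"
    )

    Path("results/tables").mkdir(parents=True, exist_ok=True)
    res.to_csv("results/tables/recovery.tsv", sep="\t", index=False,
               float_format="%.6g")
    nres.to_csv("results/tables/null_recovery.tsv", sep="\t", index=False,
                float_format="%.6g")


if __name__ == "__main__":
    main()
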