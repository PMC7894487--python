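"""Validation GLMM: taxonomic orders instead of the phylogeny.

Refits model 1 with order-level random intercepts in place of the
phylogenetic covariance; fixed-effect estimates should be qualitatively
comparable to the phylogenetic fit.
"""

from natdiv import io as nio
from natdiv.design import build_design, model1
from natdiv.metrics import build_family_dataset
from natdiv.pglmm import MCMCSettings, glmm_fit, posterior_summary

SEED = 3


def main():
    tree, regions, data, _ = nio.read_bundle("results/bundle")
    dataset, _ = build_family_dataset(data, regions, tree)
    y, X, labels = build_design(dataset, model1())
    fit = glmm_fit(y, X, dataset["order"].to_numpy(),
                   settings=MCMCSettings(52_000, 2_000, 10, 3, SEED),
                   labels=labels)
    summ = posterior_summary(fit)
    summ.to_csv("results/summary_order_glmm.csv")
    print("order-level GLMM (model 1 fixed effects):")
    print(summ.round(4).to_string())


if __name__ == "__main__":
    main()
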