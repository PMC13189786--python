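"""Fit latent class models, compare fit indices, and name the patterns.

AIC/BIC/aBIC summarize fit-complexity trade-offs; relative entropy (0-1)
summarizes how cleanly patients are assigned; the approximate adjusted LMR
test asks whether C classes beat C-1.
"""

import sonopattern as sp
from sonopattern.lca import lmr_adjusted_test, name_patterns

cohort = sp.generate_cohort(sp.paper_emulation_config(), seed=1)
fits = {C: sp.fit_lca(cohort.features, C, n_starts=30, seed=0) for C in (1, 2, 3)}

print(f"{'C':>2} {'AIC':>10} {'BIC':>10} {'aBIC':>10} {'entropy':>8} {'LMRT p':>8}")
for C, fit in fits.items():
    aic, bic, abic = sp.information_criteria(-2 * fit.log_likelihood, fit.n_params, cohort.n)
    ent = f"{sp.relative_entropy(fit.posteriors):.3f}" if C > 1 else "/"
    lmrt = f"{lmr_adjusted_test(fit, fits[C-1], cohort.n):.3f}" if C > 1 else "/"
    print(f"{C:>2} {aic:>10.1f} {bic:>10.1f} {abic:>10.1f} {ent:>8} {lmrt:>8}")

naming = name_patterns(fits[2], cohort.feature_names)
print("\npattern naming (A = higher angular-margin prevalence):", naming)
j = cohort.feature_names.index("lateral_shadowing")
print("lateral shadowing by pattern:", fits[2].rho_feature(j)[:, 1].round(2))
# The two-class model minimizes BIC; the strongly separated profile features
# (e.g. lateral shadowing ~0.76 vs ~0.07) drive the high entropy.
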