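"""Canned simulation experiments: the null-error and heritable-clearance studies.

Two experiments summarize what the package is for.

The *null-error* study asks what happens to downstream genetics when image-
derived BW differs from scale BW only by non-genetic noise: simulate a
cohort, add i.i.d. noise at the deep-regression error scale (~1.5% of mean
BW) to obtain image BW, define trait measurement error (TME) as the
absolute difference, and estimate the genomic heritability of TME plus the
top-marker agreement statistics between the scale-BW, image-BW and TME
association scans.  The expected pattern: h2(TME) ~ 0, scale-BW top-10
markers all inside the image-BW top-100, none inside the TME top-100.

The *heritable-clearance* study instantiates the hypothesized failure mode:
a low-frequency clearance-raising variant segregates in the cohort, and
image BW is obtained by model-based volumetric estimation that assumes
every animal stands at the reference ventral clearance.  Carriers are then
systematically over-estimated and TME acquires real additive genetic
variance.
"""

from __future__ import annotations

from numpy.random import SeedSequence, default_rng

from . import bwreg, quantgen, simdata, tme

__all__ = ["null_error_analysis", "clearance_error_h2"]


def null_error_analysis(
    seed: int,
    h2_bw: float = 0.4,
    noise_frac: float = 0.015,
    k_top: int = 10,
    k_ref: int = 100,
) -> dict:
    """Run the null-error study once and return its headline quantities.

    Simulates the default cohort (n=800, m=10,000 unlinked SNPs, 10 BW QTL
    of equal variance, fixed effects, paternal half-sib families), sets
    image BW = scale BW + N(0, (noise_frac * mean BW)^2), and computes the
    REML genomic heritability of TME together with the two rank-agreement
    counts (scale top-``k_top`` within image / TME top-``k_ref``).
    """
    cfg = simdata.SimConfig(seed=seed, h2_bw=h2_bw)
    r_geno, r_trait, r_noise = [default_rng(s) for s in SeedSequence(seed).spawn(3)]
    geno = simdata.simulate_genotypes(cfg, r_geno)
    arch, pheno = simdata.simulate_trait(geno, cfg, r_trait)
    y = pheno["scale_bw"].to_numpy()
    image = y + r_noise.normal(0.0, noise_frac * y.mean(), size=y.size)
    tme_v = tme.compute_tme(y, image)

    fgeno = quantgen.maf_filter(geno)
    _, grm = quantgen.build_grm(fgeno)
    X = simdata.design_matrix(pheno)
    vc_tme = quantgen.reml_fit(tme_v, X, grm)
    g_scale = quantgen.gwas_scan(y, X, fgeno, grm)
    g_image = quantgen.gwas_scan(image, X, fgeno, grm)
    g_tme = quantgen.gwas_scan(tme_v, X, fgeno, grm, vc_tme)
    return {
        "h2_tme": vc_tme.h2,
        "se_h2_tme": vc_tme.se_h2,
        "agreement": tme.topk_agreement(g_scale, g_image, k_top, k_ref),
        "tme_overlap": tme.topk_agreement(g_scale, g_tme, k_top, k_ref),
        "n": geno.n,
        "m": fgeno.m,
    }


def clearance_error_h2(seed: int, h2_clearance: float = 0.5) -> float:
    """One replicate of the heritable-clearance failure scenario.

    The cohort segregates a single low-frequency clearance-raising variant
    (heritability ``h2_clearance`` of the clearance trait); image BW comes
    from the volumetric estimator calibrated at the reference clearance.
    Returns the REML genomic heritability of TME = |scale - image|.
    """
    cfg = simdata.SimConfig(seed=seed, h2_clearance=h2_clearance)
    rngs = [default_rng(s) for s in SeedSequence(seed).spawn(5)]
    geno = simdata.simulate_genotypes(cfg, rngs[0])
    arch, pheno = simdata.simulate_trait(geno, cfg, rngs[1])
    _, clearance = simdata.simulate_clearance(
        geno, cfg, rngs[2], exclude_qtl=arch.qtl_indices
    )
    dev = simdata.simulate_shape_deviations(cfg, rngs[3])
    y = pheno["scale_bw"].to_numpy()
    feats = simdata.simulate_features(y, clearance, cfg, rngs[4], shape_dev=dev)
    model = bwreg.volumetric_model(*simdata.volumetric_calibration(cfg))
    image = model.predict(feats[["volume"]])

    fgeno = quantgen.maf_filter(geno)
    _, grm = quantgen.build_grm(fgeno)
    X = simdata.design_matrix(pheno)
    return quantgen.reml_fit(tme.compute_tme(y, image), X, grm).h2
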