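"""Extract the full 1117-feature radiomic vector for one synthetic case.

The chain is: resample to 1 mm isotropic voxels -> normalize to
[m - 3s, m + 3s] and quantize to 64 gray levels inside the contour ->
compute 13 shape + 18 first-order + 74 texture features on the original
image and 92 features on each of 11 derived images (3 LoG widths, 8
wavelet sub-bands).
"""

from npcradiomics import CohortSpec, extract_all, generate_tumor_case

vol, mask = generate_tumor_case(CohortSpec(seed=1), "IFR", 0)
features, provenance = extract_all(vol, mask)

print(f"features per case: {provenance['n_features']}")
print(f"non-finite features: {len(provenance['nan_features'])}")
for key in ("shape_Volume", "F_RMS", "glcm_CT", "W_HLL__gldm_DE", "LoG_1.5__ngtdm_Complexity"):
    print(f"  {key} = {features[key]:.4g}")
# shape_Volume is the ROI volume in mm^3; glcm_CT (cluster tendency) and
# the wavelet/LoG texture values quantify intratumoral heterogeneity at
# different spatial scales.
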