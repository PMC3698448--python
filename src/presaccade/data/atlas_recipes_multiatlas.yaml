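# ROI recipes for real multi-atlas label volumes (Hammers, Harvard-Oxford,
# LPBA, Brodmann).  Label tokens follow "<atlas>_<index>" naming; volumes
# from different atlases registered to the same head can be merged into one
# label volume with prefixed label names before applying these recipes.
#
# These recipes are shipped as *data*: the phantom pipeline does not use
# them (it has its own blob atlas), but they document how the composite
# regions -- cingulate subdivisions split at the anterior commissure, and an
# intraparietal-sulcus ROI built as the overlap of 3-mm dilations of the
# inferior and superior parietal lobules -- are expressed in the recipe
# vocabulary.
rois:
  - name: frontal_pole
    laterality: midline
    recipe:
      - {op: union, labels: [harvardoxford_1]}
  - name: orbital_frontal
    laterality: midline
    recipe:
      - {op: union, labels: [hammers_52, hammers_53, hammers_68, hammers_69,
                             harvardoxford_25, lpba_29, lpba_30, lpba_33, lpba_34]}
  - name: ventral_acc
    laterality: midline
    recipe:
      - {op: union, labels: [hammers_76, hammers_77, hammers_78, hammers_79,
                             hammers_80, hammers_81, harvardoxford_25]}
      - {op: union, labels: [harvardoxford_28, harvardoxford_29]}
      - {op: mask_ac, keep: [inferior]}
  - name: dorsal_acc
    laterality: midline
    recipe:
      - {op: union, labels: [hammers_24, hammers_25, harvardoxford_28, harvardoxford_29]}
      - {op: mask_ac, keep: [anterior, superior]}
  - name: posterior_cingulate
    laterality: midline
    recipe:
      - {op: union, labels: [hammers_26, hammers_27, harvardoxford_30]}
      - {op: mask_ac, keep: [posterior]}
  - name: superior_parietal
    laterality: midline
    recipe:
      - {op: union, labels: [hammers_62, hammers_63, harvardoxford_18, lpba_43, lpba_44]}
  - name: supramarginal_left
    laterality: left
    recipe:
      - {op: union, labels: [lpba_45]}
  - name: supramarginal_right
    laterality: right
    recipe:
      - {op: union, labels: [lpba_46]}
  - name: angular_left
    laterality: left
    recipe:
      - {op: union, labels: [lpba_47]}
  - name: angular_right
    laterality: right
    recipe:
      - {op: union, labels: [lpba_48]}
  - name: intraparietal_sulcus_left
    laterality: left
    recipe:
      # inferior parietal lobe = supramarginal + angular + parietal remainder
      - {op: union, labels: [lpba_45, lpba_47, hammers_32]}
      - {op: dilate, mm: 3.0}
      # overlap with the 3-mm dilated superior parietal lobe
      - op: intersect
        with:
          - {op: union, labels: [hammers_62, lpba_43]}
          - {op: dilate, mm: 3.0}
  - name: intraparietal_sulcus_right
    laterality: right
    recipe:
      - {op: union, labels: [lpba_46, lpba_48, hammers_33]}
      - {op: dilate, mm: 3.0}
      - op: intersect
        with:
          - {op: union, labels: [hammers_63, lpba_44]}
          - {op: dilate, mm: 3.0}
  - name: pre_post_central_left
    laterality: left
    recipe:
      - {op: union, labels: [hammers_50, hammers_60, harvardoxford_7, lpba_27, lpba_41]}
  - name: pre_post_central_right
    laterality: right
    recipe:
      - {op: union, labels: [hammers_51, hammers_61, harvardoxford_7, lpba_28, lpba_42]}
  - name: ba6_8_left
    laterality: left
    recipe:
      - {op: union, labels: [brodmann_6_left, brodmann_8_left]}
  - name: ba6_8_right
    laterality: right
    recipe:
      - {op: union, labels: [brodmann_6_right, brodmann_8_right]}
  - name: dlpfc_left
    laterality: left
    recipe:
      - {op: union, labels: [brodmann_9_left, brodmann_46_left]}
  - name: dlpfc_right
    laterality: right
    recipe:
      - {op: union, labels: [brodmann_9_right, brodmann_46_right]}
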