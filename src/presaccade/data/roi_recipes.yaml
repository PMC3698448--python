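# ROI recipes for the spherical phantom atlas.
#
# Each entry names an ROI, its laterality, and an ordered recipe over atlas
# labels.  The vocabulary (union, mask_ac, dilate, intersect) mirrors how
# composite anatomical ROIs are assembled from multi-atlas labels; on the
# phantom most regions are single blobs, with the cingulate subdivisions
# demonstrating the AC-relative masks.
rois:
  - name: ventral_acc
    laterality: midline
    recipe:
      - {op: union, labels: [ventral_acc]}
  - name: orbital_frontal
    laterality: midline
    recipe:
      - {op: union, labels: [orbital_frontal]}
  - name: dorsal_acc
    laterality: midline
    recipe:
      - {op: union, labels: [dorsal_acc]}
      - {op: mask_ac, keep: [anterior, superior]}
  - name: posterior_cingulate
    laterality: midline
    recipe:
      - {op: union, labels: [posterior_cingulate]}
      - {op: mask_ac, keep: [posterior]}
  - name: frontal_pole_left
    laterality: left
    recipe:
      - {op: union, labels: [frontal_pole_left]}
  - name: frontal_pole_right
    laterality: right
    recipe:
      - {op: union, labels: [frontal_pole_right]}
  - name: superior_parietal_left
    laterality: left
    recipe:
      - {op: union, labels: [superior_parietal_left]}
  - name: superior_parietal_right
    laterality: right
    recipe:
      - {op: union, labels: [superior_parietal_right]}
  - name: precentral_left
    laterality: left
    recipe:
      - {op: union, labels: [precentral_left]}
  - name: precentral_right
    laterality: right
    recipe:
      - {op: union, labels: [precentral_right]}
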