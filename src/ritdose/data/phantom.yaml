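# Default parametric mouse-like phantom.
#
# Named organ spheres are mutually disjoint and contained in the
# rest-of-body background box (the trunk); region lookup priority is the
# listing order, background last.  Radii are chosen so that sphere volume x
# material density gives typical organ masses for a ~25 g mouse; the lungs
# use the low-density lung material.
regions:
  - name: tumor
    shape: sphere
    material: soft_tissue
    center_mm: [-24.0, 3.5, 3.5]
    radius_mm: 4.098            # 0.30 g
  - name: spleen
    shape: sphere
    material: soft_tissue
    center_mm: [9.0, 5.0, 0.0]
    radius_mm: 2.840            # 0.10 g
  - name: kidneys
    shape: sphere
    material: soft_tissue
    center_mm: [14.0, -3.5, 0.0]
    radius_mm: 4.098            # 0.30 g
  - name: liver
    shape: sphere
    material: soft_tissue
    center_mm: [0.5, 0.0, 0.0]
    radius_mm: 6.680            # 1.30 g
  - name: heart
    shape: sphere
    material: soft_tissue
    center_mm: [-13.0, 3.5, 3.0]
    radius_mm: 3.252            # 0.15 g
  - name: lungs
    shape: sphere
    material: lung
    center_mm: [-11.0, -3.2, -3.2]
    radius_mm: 4.944            # 0.15 g at 0.296 g/cm3
  - name: brain
    shape: sphere
    material: soft_tissue
    center_mm: [-32.0, 0.0, 0.0]
    radius_mm: 4.512            # 0.40 g
  - name: rest_of_body
    shape: box
    material: soft_tissue
    center_mm: [0.0, 0.0, 0.0]
    size_mm: [80.0, 17.5, 17.5]
    background: true
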