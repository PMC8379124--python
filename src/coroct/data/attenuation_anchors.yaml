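# Reference attenuation anchors (median HU, with interquartile range) by
# reconstruction energy.  "conventional" is the polychromatic 120 kVp image;
# "vmi<E>" is the virtual monochromatic reconstruction at E keV.
#
# The lumen entries are in vivo coronary/aortic blood-pool medians used to
# derive the energy scaling of iodine enhancement.  Fat, muscle and
# trabecular bone are tissue ROI anchors.  PMMA and the blood baseline are
# simulator defaults (not measured anchors) and may be overridden.

energies: [conventional, vmi40, vmi55, vmi70, vmi85, vmi100, vmi115, vmi130]

lumen_segments:
  proximal_rca:
    median: {conventional: 425.0, vmi40: 743.5, vmi55: 413.4, vmi70: 258.7, vmi85: 188.2, vmi100: 143.5, vmi115: 118.1, vmi130: 102.0}
    iqr:    {conventional: 116.9, vmi40: 262.0, vmi55: 130.6, vmi70: 80.4,  vmi85: 57.6,  vmi100: 45.2,  vmi115: 38.2,  vmi130: 36.8}
  distal_rca:
    median: {conventional: 414.9, vmi40: 606.3, vmi55: 346.0, vmi70: 222.7, vmi85: 163.9, vmi100: 130.4, vmi115: 109.4, vmi130: 95.0}
    iqr:    {conventional: 143.1, vmi40: 288.4, vmi55: 143.3, vmi70: 79.1,  vmi85: 59.3,  vmi100: 47.1,  vmi115: 45.2,  vmi130: 44.0}
  left_main:
    median: {conventional: 451.1, vmi40: 828.0, vmi55: 463.5, vmi70: 284.0, vmi85: 205.0, vmi100: 160.1, vmi115: 131.1, vmi130: 114.8}
    iqr:    {conventional: 123.0, vmi40: 252.0, vmi55: 128.3, vmi70: 69.3,  vmi85: 50.1,  vmi100: 42.9,  vmi115: 38.2,  vmi130: 38.5}
  distal_lad:
    median: {conventional: 292.5, vmi40: 413.0, vmi55: 236.3, vmi70: 160.0, vmi85: 119.8, vmi100: 94.6,  vmi115: 80.0,  vmi130: 69.5}
    iqr:    {conventional: 135.8, vmi40: 244.0, vmi55: 134.0, vmi70: 70.9,  vmi85: 55.5,  vmi100: 52.6,  vmi115: 48.6,  vmi130: 45.3}
  distal_lcx:
    median: {conventional: 337.9, vmi40: 496.1, vmi55: 279.6, vmi70: 185.2, vmi85: 139.8, vmi100: 116.7, vmi115: 99.0,  vmi130: 90.7}
    iqr:    {conventional: 115.5, vmi40: 265.6, vmi55: 146.4, vmi70: 91.5,  vmi85: 63.8,  vmi100: 56.7,  vmi115: 52.9,  vmi130: 49.0}
  ascending_aorta:
    median: {conventional: 466.0, vmi40: 871.9, vmi55: 486.0, vmi70: 301.4, vmi85: 211.4, vmi100: 161.4, vmi115: 130.6, vmi130: 114.2}
    iqr:    {conventional: 154.1, vmi40: 246.9, vmi55: 130.6, vmi70: 76.3,  vmi85: 52.3,  vmi100: 40.8,  vmi115: 29.5,  vmi130: 27.3}

# pooled median over all lumen segments; drives the iodine energy scaling
lumen_median:
  median: {conventional: 397.4, vmi40: 691.8, vmi55: 380.1, vmi70: 243.2, vmi85: 172.6, vmi100: 135.9, vmi115: 113.0, vmi130: 99.0}
  iqr:    {conventional: 131.4, vmi40: 259.9, vmi55: 136.4, vmi70: 77.9,  vmi85: 56.4,  vmi100: 47.5,  vmi115: 42.1,  vmi130: 40.1}

tissues:
  fat:
    median: {conventional: -87.1, vmi40: -178.0, vmi55: -124.0, vmi70: -101.0, vmi85: -90.0, vmi100: -85.0, vmi115: -81.2, vmi130: -78.5}
    iqr:    {conventional: 28.6,  vmi40: 47.6,   vmi55: 25.3,   vmi70: 19.9,   vmi85: 17.3,  vmi100: 16.4,  vmi115: 17.9,  vmi130: 15.5}
  muscle:
    median: {conventional: 103.4, vmi40: 163.1, vmi55: 108.0, vmi70: 81.8, vmi85: 70.5, vmi100: 63.1, vmi115: 58.4, vmi130: 56.0}
    iqr:    {conventional: 36.8,  vmi40: 56.9,  vmi55: 33.1,  vmi70: 21.3, vmi85: 15.2, vmi100: 13.3, vmi115: 14.1, vmi130: 13.0}
  trabecular_bone:
    median: {conventional: 201.8, vmi40: 481.6, vmi55: 297.4, vmi70: 208.5, vmi85: 169.6, vmi100: 149.0, vmi115: 138.0, vmi130: 130.6}
    iqr:    {conventional: 100.1, vmi40: 399.1, vmi55: 318.2, vmi70: 236.5, vmi85: 142.6, vmi100: 126.0, vmi115: 112.5, vmi130: 103.0}

# simulator defaults, not anchors ----------------------------------------

# PMMA slab background; ~120 HU at 120 kVp with a mild rise toward low keV
pmma:
  median: {conventional: 120.0, vmi40: 126.0, vmi55: 123.0, vmi70: 121.0, vmi85: 119.0, vmi100: 117.0, vmi115: 116.0, vmi130: 115.0}

# baseline HU of the zero-iodine carrier (blood/saline), assumed flat in energy
blood_base_hu: 40.0

# calibration: a mixture at this concentration reads this HU on conventional
iodine_anchor:
  concentration_mg_ml: 18.5
  hu_conventional: 400.0
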