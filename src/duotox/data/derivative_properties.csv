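compound_id,property_name,value,context
CIP,frequency,26.78,
3-CH2-C3H5-CIP,frequency,25.79,
3-CH2-C3H4Cl-CIP,frequency,18.25,
3-CH2CH2CH3-CIP,frequency,20.12,
CIP,total_energy,-1147.95,
3-CH2-C3H5-CIP,total_energy,-1187.27,
3-CH2-C3H4Cl-CIP,total_energy,-1646.78,
3-CH2CH2CH3-CIP,total_energy,-1149.18,
CIP,log_kow,0.28,
3-CH2-C3H5-CIP,log_kow,0.49,
3-CH2-C3H4Cl-CIP,log_kow,0.67,
3-CH2CH2CH3-CIP,log_kow,0.19,
CIP,t_half_river,8.72e13,
3-CH2-C3H5-CIP,t_half_river,6.71e13,
3-CH2-C3H4Cl-CIP,t_half_river,2.00e14,
3-CH2CH2CH3-CIP,t_half_river,3.84e13,
CIP,dock_total_score,73.22,1FC6
3-CH2-C3H5-CIP,dock_total_score,83.06,1FC6
3-CH2-C3H4Cl-CIP,dock_total_score,84.08,1FC6
3-CH2CH2CH3-CIP,dock_total_score,79.15,1FC6
CIP,dock_total_score,59.22,5Z9P
3-CH2-C3H5-CIP,dock_total_score,70.89,5Z9P
3-CH2-C3H4Cl-CIP,dock_total_score,69.01,5Z9P
3-CH2CH2CH3-CIP,dock_total_score,67.18,5Z9P
CIP,dock_total_score,71.08,2XNC
3-CH2-C3H5-CIP,dock_total_score,77.82,2XNC
3-CH2-C3H4Cl-CIP,dock_total_score,82.56,2XNC
3-CH2CH2CH3-CIP,dock_total_score,77.17,2XNC
CIP,dock_binding_energy,-81.58,1FC6
3-CH2-C3H5-CIP,dock_binding_energy,-90.68,1FC6
3-CH2-C3H4Cl-CIP,dock_binding_energy,-94.77,1FC6
3-CH2CH2CH3-CIP,dock_binding_energy,-105.66,1FC6
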