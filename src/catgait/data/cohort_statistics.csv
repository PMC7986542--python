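cohort,parameter,mean,sd
study1_veh_mod,p_lda,0.059,0.015
study1_veh_mod,forepaw_swing_time,0.11,0.01
study1_veh_mod,forepaw_stride_length,10.5,1.2
study1_veh_mod,forepaw_duty_cycle,64.7,5.0
study1_veh_mod,hindpaw_bos,3.6,0.3
study1_veh_mod,regularity_index,93.8,2.6
study1_veh_mod,body_speed,32.9,6.5
study1_veh_mod,ab_sequence,64.1,22.9
study1_veh_mod,forepaw_max_contact_at,48.0,3.9
study1_veh_mod,hindpaw_stride_length,12.2,1.0
study1_veh_modsev,p_lda,0.037,0.016
study1_veh_modsev,forepaw_swing_time,0.11,0.01
study1_veh_modsev,forepaw_stride_length,9.6,0.8
study1_veh_modsev,forepaw_duty_cycle,68.3,3.4
study1_veh_modsev,hindpaw_bos,4.1,0.7
study1_veh_modsev,regularity_index,85.9,10.5
study1_veh_modsev,body_speed,27.5,3.5
study1_veh_modsev,ab_sequence,62.4,16.8
study1_veh_modsev,forepaw_max_contact_at,52.9,3.2
study1_veh_modsev,hindpaw_stride_length,11.7,1.6
study2_sci,p_lda,0.029,0.021
study2_sci,forepaw_swing_time,0.09,0.01
study2_sci,forepaw_stride_length,9.0,1.5
study2_sci,forepaw_duty_cycle,72.2,3.2
study2_sci,hindpaw_bos,5.1,0.8
study2_sci,regularity_index,89.8,7.3
study2_sci,body_speed,27.9,6.7
study2_sci,ab_sequence,55.6,15.4
study2_sci,forepaw_max_contact_at,43.5,3.9
study2_sci,hindpaw_stride_length,11.6,1.9
study2_sci_prog,p_lda,0.059,0.027
study2_sci_prog,forepaw_swing_time,0.12,0.02
study2_sci_prog,forepaw_stride_length,10.4,1.6
study2_sci_prog,forepaw_duty_cycle,67.6,2.0
study2_sci_prog,hindpaw_bos,4.6,0.8
study2_sci_prog,regularity_index,97.8,2.4
study2_sci_prog,body_speed,30.5,8.1
study2_sci_prog,ab_sequence,66.3,19.5
study2_sci_prog,forepaw_max_contact_at,43.9,1.7
study2_sci_prog,hindpaw_stride_length,12.1,1.2
study3_young,p_lda,0.034,0.027
study3_young,forepaw_swing_time,0.10,0.01
study3_young,forepaw_stride_length,11.0,2.1
study3_young,forepaw_duty_cycle,67.4,6.6
study3_young,hindpaw_bos,4.9,0.8
study3_young,regularity_index,87.0,14.7
study3_young,body_speed,37.2,9.7
study3_young,ab_sequence,56.8,20.3
study3_young,forepaw_max_contact_at,48.6,5.9
study3_young,hindpaw_stride_length,13.5,2.6
study3_old,p_lda,-0.015,0.018
study3_old,forepaw_swing_time,0.088,0.009
study3_old,forepaw_stride_length,9.1,1.1
study3_old,forepaw_duty_cycle,74.0,3.1
study3_old,hindpaw_bos,6.4,0.7
study3_old,regularity_index,85.5,5.4
study3_old,body_speed,26.4,5.0
study3_old,ab_sequence,43.1,12.4
study3_old,forepaw_max_contact_at,60.8,4.4
study3_old,hindpaw_stride_length,12.3,1.1
study2_30dpi,p_lda,0.025,0.017
study2_30dpi,forepaw_swing_time,0.09,0.01
study2_30dpi,forepaw_stride_length,9.2,0.8
study2_30dpi,forepaw_duty_cycle,72.8,3.1
study2_30dpi,hindpaw_bos,5.0,0.7
study2_30dpi,regularity_index,91.2,2.8
study2_30dpi,body_speed,29.3,5.9
study2_30dpi,ab_sequence,44.2,11.1
study2_30dpi,forepaw_max_contact_at,44.3,5.7
study2_30dpi,hindpaw_stride_length,12.0,1.7
study4_30dpi,p_lda,0.075,0.029
study4_30dpi,forepaw_swing_time,0.11,0.02
study4_30dpi,forepaw_stride_length,13.3,2.9
study4_30dpi,forepaw_duty_cycle,58.8,7.6
study4_30dpi,hindpaw_bos,3.6,0.9
study4_30dpi,regularity_index,78.8,29.4
study4_30dpi,body_speed,42.8,10.6
study4_30dpi,ab_sequence,62.9,28.9
study4_30dpi,forepaw_max_contact_at,41.3,6.5
study4_30dpi,hindpaw_stride_length,16.8,2.3
study5_uninjured,p_lda,0.112,0.012
study5_uninjured,forepaw_swing_time,0.14,0.01
study5_uninjured,forepaw_stride_length,13.1,1.4
study5_uninjured,forepaw_duty_cycle,61.3,4.1
study5_uninjured,hindpaw_bos,2.1,0.1
study5_uninjured,regularity_index,98.2,1.6
study5_uninjured,body_speed,32.6,8.7
study5_uninjured,ab_sequence,93.1,11.1
study5_uninjured,forepaw_max_contact_at,43.1,3.0
study5_uninjured,hindpaw_stride_length,12.9,1.3
study5_sci,p_lda,0.120,0.010
study5_sci,forepaw_swing_time,0.14,0.01
study5_sci,forepaw_stride_length,15.2,0.6
study5_sci,forepaw_duty_cycle,57.9,1.2
study5_sci,hindpaw_bos,2.0,0.5
study5_sci,regularity_index,99.4,1.4
study5_sci,body_speed,41.5,3.9
study5_sci,ab_sequence,83.3,9.1
study5_sci,forepaw_max_contact_at,40.6,2.9
study5_sci,hindpaw_stride_length,15.1,0.6
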