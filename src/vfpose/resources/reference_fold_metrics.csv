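table,fold,method,metric,mean,sd
keypoint,0,heatmap,rmse_lv,5.45,13.89
keypoint,0,heatmap,rmse_a,8.45,19.38
keypoint,0,heatmap,rmse_rv,5.60,11.57
keypoint,0,direct,rmse_lv,8.49,6.15
keypoint,0,direct,rmse_a,8.66,6.82
keypoint,0,direct,rmse_rv,7.74,4.70
keypoint,0,segmentation,rmse_lv,6.51,8.46
keypoint,0,segmentation,rmse_a,7.08,6.07
keypoint,0,segmentation,rmse_rv,6.55,7.36
keypoint,1,heatmap,rmse_lv,5.72,13.87
keypoint,1,heatmap,rmse_a,5.79,15.13
keypoint,1,heatmap,rmse_rv,6.66,16.41
keypoint,1,direct,rmse_lv,9.38,7.60
keypoint,1,direct,rmse_a,8.44,8.05
keypoint,1,direct,rmse_rv,10.12,10.43
keypoint,1,segmentation,rmse_lv,8.75,11.56
keypoint,1,segmentation,rmse_a,10.65,9.91
keypoint,1,segmentation,rmse_rv,9.03,12.54
keypoint,2,heatmap,rmse_lv,3.47,3.65
keypoint,2,heatmap,rmse_a,5.03,12.46
keypoint,2,heatmap,rmse_rv,5.17,12.31
keypoint,2,direct,rmse_lv,9.03,7.44
keypoint,2,direct,rmse_a,8.96,8.49
keypoint,2,direct,rmse_rv,7.75,6.49
keypoint,2,segmentation,rmse_lv,6.92,8.95
keypoint,2,segmentation,rmse_a,6.45,6.32
keypoint,2,segmentation,rmse_rv,6.68,9.07
keypoint,3,heatmap,rmse_lv,4.90,13.73
keypoint,3,heatmap,rmse_a,4.89,10.68
keypoint,3,heatmap,rmse_rv,6.89,18.49
keypoint,3,direct,rmse_lv,7.47,6.27
keypoint,3,direct,rmse_a,8.66,6.42
keypoint,3,direct,rmse_rv,7.83,6.24
keypoint,3,segmentation,rmse_lv,7.15,10.64
keypoint,3,segmentation,rmse_a,7.72,7.44
keypoint,3,segmentation,rmse_rv,6.89,9.39
keypoint,4,heatmap,rmse_lv,5.92,12.98
keypoint,4,heatmap,rmse_a,8.64,18.81
keypoint,4,heatmap,rmse_rv,7.70,13.53
keypoint,4,direct,rmse_lv,7.66,6.91
keypoint,4,direct,rmse_a,9.74,8.26
keypoint,4,direct,rmse_rv,8.36,8.03
keypoint,4,segmentation,rmse_lv,6.51,8.98
keypoint,4,segmentation,rmse_a,8.45,10.57
keypoint,4,segmentation,rmse_rv,7.04,8.91
aga,0,heatmap,aga_mae,6.39,1.58
aga,0,heatmap,aga_rmse,15.01,5.63
aga,0,direct,aga_mae,8.74,1.25
aga,0,direct,aga_rmse,13.17,1.56
aga,0,segmentation,aga_mae,8.88,2.56
aga,0,segmentation,aga_rmse,11.84,2.41
aga,1,heatmap,aga_mae,6.54,1.44
aga,1,heatmap,aga_rmse,14.62,3.42
aga,1,direct,aga_mae,13.03,2.35
aga,1,direct,aga_rmse,18.59,2.99
aga,1,segmentation,aga_mae,5.13,1.00
aga,1,segmentation,aga_rmse,6.87,1.80
aga,2,heatmap,aga_mae,4.40,1.65
aga,2,heatmap,aga_rmse,9.30,2.19
aga,2,direct,aga_mae,9.94,1.56
aga,2,direct,aga_rmse,14.04,2.29
aga,2,segmentation,aga_mae,4.99,0.90
aga,2,segmentation,aga_rmse,6.46,0.86
aga,3,heatmap,aga_mae,3.52,0.52
aga,3,heatmap,aga_rmse,6.53,1.32
aga,3,direct,aga_mae,9.45,1.73
aga,3,direct,aga_rmse,17.32,3.88
aga,3,segmentation,aga_mae,6.53,0.79
aga,3,segmentation,aga_rmse,9.44,1.94
aga,4,heatmap,aga_mae,8.48,2.95
aga,4,heatmap,aga_rmse,22.25,8.10
aga,4,direct,aga_mae,10.66,1.52
aga,4,direct,aga_rmse,16.22,3.48
aga,4,segmentation,aga_mae,5.61,1.55
aga,4,segmentation,aga_rmse,10.12,3.30
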