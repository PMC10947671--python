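# Independent base-R implementation of the incidence-based coverage and
# Hill-number rarefaction/extrapolation estimators, used ONCE to generate the
# frozen golden fixture `golden_incidence.csv`. Kept for provenance; the test
# suite reads the CSV and never invokes R.
#
# Conventions mirrored by the Python implementation:
#   * coverage at integer t < T: unbiased rarefaction estimator;
#     at t >= T: 1 - (Q1/U) A^(t-T+1) with bias-corrected A when Q2 = 0
#   * effort inversion: piecewise-linear between integer efforts below T,
#     closed form on the extrapolation branch
#   * non-integer effort for D: linear interpolation between adjacent integers

set.seed(20230916)

cov_factor <- function(T, Y) {
  Q1 <- sum(Y == 1); Q2 <- sum(Y == 2)
  if (Q1 == 0) return(1)
  if (Q2 > 0) (T - 1) * Q1 / ((T - 1) * Q1 + 2 * Q2)
  else (T - 1) * (Q1 - 1) / ((T - 1) * (Q1 - 1) + 2)
}

cov_int <- function(T, Y, t) {  # coverage at integer effort t in [0, T]
  U <- sum(Y); Q1 <- sum(Y == 1)
  if (t <= 0) return(0)
  if (t >= T) return(1 - Q1 / U * cov_factor(T, Y)^(t - T + 1))
  keep <- (T - Y) >= t
  if (!any(keep)) return(1)
  1 - sum(Y[keep] / U * choose(T - Y[keep], t) / choose(T - 1, t))
}

cov_ext <- function(T, Y, t) {  # t >= T, continuous
  U <- sum(Y); Q1 <- sum(Y == 1)
  if (Q1 == 0) return(1)
  1 - Q1 / U * cov_factor(T, Y)^(t - T + 1)
}

m_for_coverage <- function(T, Y, target) {
  grid <- sapply(0:T, function(t) cov_int(T, Y, t))
  grid <- cummax(grid)
  if (target <= grid[T + 1]) {
    j <- which(grid >= target)[1] - 1  # effort value (0-based)
    if (j == 0) return(0)
    clo <- grid[j]; chi <- grid[j + 1]
    if (chi <= clo) return(j)
    return(j - 1 + (target - clo) / (chi - clo))
  }
  U <- sum(Y); Q1 <- sum(Y == 1); A <- cov_factor(T, Y)
  T - 1 + log((1 - target) * U / Q1) / log(A)
}

EQk <- function(T, Y, t) {  # expected species counts by incidence k in subsample
  sapply(1:t, function(k) sum(choose(Y, k) * choose(T - Y, t - k)) / choose(T, t))
}

D0_at <- function(T, Y, t) {
  S <- length(Y); Q1 <- sum(Y == 1); Q2 <- sum(Y == 2)
  if (t <= T) return(S - sum(choose(T - Y, t)) / choose(T, t))
  Q0 <- if (Q2 > 0) (T - 1) / T * Q1^2 / (2 * Q2) else (T - 1) / T * Q1 * (Q1 - 1) / 2
  if (Q1 == 0 || Q0 <= 0) return(S)
  S + Q0 * (1 - (1 - Q1 / (Q1 + T * Q0))^(t - T))
}

D1_int <- function(T, Y, t) {
  U <- sum(Y); Ut <- t * U / T
  eq <- EQk(T, Y, t); k <- 1:t
  pos <- eq > 0
  exp(-sum((k[pos] / Ut) * log(k[pos] / Ut) * eq[pos]))
}

H_asymptotic <- function(T, Y) {
  U <- sum(Y); Q1 <- sum(Y == 1); Q2 <- sum(Y == 2)
  main <- sum(Y / T * (digamma(T) - digamma(Y)))
  rare <- 0
  if (Q1 > 0) {
    a <- if (Q2 > 0) 2 * Q2 / ((T - 1) * Q1 + 2 * Q2) else 2 / ((T - 1) * (Q1 - 1) + 2)
    if (a < 1) {
      r <- 1:(T - 1)
      rare <- Q1 / T * (1 - a)^(1 - T) * (-log(a) - sum((1 - a)^r / r))
    }
  }
  h <- T / U * (main + rare) + log(U / T)
  max(h, -sum(Y / U * log(Y / U)))
}

D1_at <- function(T, Y, t) {
  U <- sum(Y)
  if (t > T) {
    hobs <- -sum(Y / U * log(Y / U))
    d1 <- exp(T / t * hobs + (1 - T / t) * H_asymptotic(T, Y))
    return(min(d1, D0_at(T, Y, t)))  # ordering cap on the extrapolation branch
  }
  if (t == floor(t)) return(D1_int(T, Y, t))
  lo <- floor(t); hi <- ceiling(t); w <- t - lo
  dlo <- if (lo >= 1) D1_int(T, Y, lo) else 1
  (1 - w) * dlo + w * D1_int(T, Y, hi)
}

D2_closed <- function(T, Y, t) {
  U <- sum(Y); Ut <- t * U / T
  den <- t * (t - 1) / (T * (T - 1)) * sum(Y * (Y - 1)) + Ut
  Ut^2 / den
}

D2_at <- function(T, Y, t) {  # linear interpolation between integers below T
  if (t > T) return(min(D2_closed(T, Y, t), D1_at(T, Y, t)))  # ordering cap
  if (t == floor(t)) return(D2_closed(T, Y, t))
  lo <- floor(t); hi <- ceiling(t); w <- t - lo
  dlo <- if (lo >= 1) D2_closed(T, Y, lo) else 1
  (1 - w) * dlo + w * D2_closed(T, Y, hi)
}

D0_interp <- function(T, Y, t) {
  if (t > T || t == floor(t)) return(D0_at(T, Y, t))
  lo <- floor(t); hi <- ceiling(t); w <- t - lo
  dlo <- if (lo >= 1) D0_at(T, Y, lo) else 0
  (1 - w) * dlo + w * D0_at(T, Y, hi)
}

rows <- list()
n_fix <- 25
i <- 0
while (i < n_fix) {
  T <- sample(5:30, 1)
  S <- sample(4:15, 1)
  Y <- pmin(pmax(rnbinom(S, size = 1.2, mu = T / 3), 1), T)
  target <- 0.8
  mstar <- m_for_coverage(T, Y, target)
  if (!is.finite(mstar) || mstar > 2 * T || mstar < 1) next  # stay in the pipeline's regime
  i <- i + 1
  rows[[i]] <- data.frame(
    id = i, T = T, Y = paste(Y, collapse = ";"),
    C_T = cov_int(T, Y, T), C_2T = cov_ext(T, Y, 2 * T),
    m_star = mstar,
    D0 = D0_interp(T, Y, mstar), D1 = D1_at(T, Y, mstar), D2 = D2_at(T, Y, mstar)
  )
}
out <- do.call(rbind, rows)
write.csv(format(out, digits = 15), file = "golden_incidence.csv", row.names = FALSE, quote = FALSE)
cat("wrote", nrow(out), "fixtures\n")
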